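# Methods

## Model

`dnamix` codes a DNA sequence symbol by symbol. At each position every
expert emits a distribution over {A, C, G, T}; the experts are
finite-context models (FCMs), their optional substitution-tolerant
sub-models (STCMs), and — in referential modes — the same machinery
trained on a reference and frozen. A soft-blend combines the experts
adaptively, and a one-hidden-layer sigmoid network consumes the experts,
the blend and a set of derived features to produce the final coding
distribution for a 32-bit range coder. All adaptive state (counters,
blend weights, features, network weights) is updated only from symbols
already coded, so the decompressor can replay the identical trajectory.

### Finite-context models

An order-k FCM keeps four 16-bit counters per context. Probabilities use
additive smoothing α = 1/alpha_den. When any counter of a context
reaches 65,535 all four are halved (integer division) before the
increment — bounded memory with gradual forgetting. For 4^k ≤ 2^24 the
store is a dense array; above that an open-addressing hash of
budget·2^16 cells (power-of-two, capped at 2^22) with linear probing,
full-context fingerprints and collision-overwrite keeps RAM constant at
the price of occasional count loss. During the first k positions a model
abstains (exact uniform output) and does not update; this convention
makes "abstain" detectable as exact equality of the four probabilities.

With the inverted-repeat flag, each update is mirrored: context = reverse
complement of the k symbols ending at the current position, symbol =
complement of the symbol k positions back. One pass over S then leaves
exactly the counts of a plain pass over S plus a plain pass over
reverse_complement(S) — the identity used as the test oracle.

### Substitution-tolerant context models

An STCM shares its FCM's counters (only its smoothing denominator and
forgetting factor differ) but maintains a private context. After each
symbol is coded it compares its top vote (argmax of the counters at the
private context) with the truth: on a hit the private context is
extended with the true symbol, on a miss with the model's own guess —
the assumed substitution. A FIFO of the last max(2t, 8) hit/miss
outcomes is kept; when the misses in it exceed the tolerance t, the
private context resets to the true trailing k symbols and the history
clears. Outcomes are evaluated against the symbol *after* coding, which
keeps encoder and decoder synchronized.

### Soft-blending

Weights start uniform and update as w_i ← w_i^{γ_i} · p_i(sym), floored
at 1e-8 and renormalised. γ comes from each model's gamma field (the
STCM uses its own tol_gamma). The exponent form follows the description
of per-model forgetting; the floor prevents weight extinction so a model
that becomes useful again can recover.

### Neural mixer

Inputs per expert (soft-blend included as a pseudo-expert): the four
stretched, centred probabilities stretch((1+f_j)/Σ(1+f_m)) − stretch(¼),
where stretch is the natural-log logit clamped to [1e-6, 1−1e-6], plus
hit, best and bits. hit/best move in ±0.1 steps, clamped to [−1, 1];
abstainers are unchanged and cannot win "best" but stay in its
comparison set. bits and nnbits are EMAs of −log₂ p(sym) + log₂ ¼ with
rates 0.15 and 0.5. Twelve further nodes carry the symbol frequencies of
the last 8, 16 and 64 symbols, affinely scaled (2f − 1); before the first
symbol they emit 0, the centred neutral value. The blend pseudo-expert
has no counters, so its stretched input is computed from its probability
vector directly.

The network is fully connected with one hidden layer, sigmoid
activations, bias nodes on input and hidden layers and Xavier-uniform
initialisation. Training is plain SGD on L = ½Σ(raw − onehot)², taken on
the raw sigmoid outputs; the normalisation (divide by the sum, after
flooring at 1e-6) is a coding-side correction only. There is no
momentum, decay or batching, and training runs for the whole sequence.
Defaults: learning rate 0.03 and 64 hidden nodes, the settings that work
without tuning on megabase-scale inputs; for the ~10–100 kb fixtures
used in the tests the package follows the published per-size practice of
a higher rate and fewer nodes (0.06, 24), since a cold network amortises
its adjustment period over fewer symbols.

The initialisation seed is a fixed format constant: only the learning
rate and hidden count are stored in the header (8 bytes), and the
learning rate is quantised to its 32-bit float representation *before*
training so compressor and decompressor train with bit-identical values.
Determinism is guaranteed on one platform/build; cross-platform
floating-point identity is not claimed.

### Range coder

32-bit range coder, byte-wise renormalisation at range < 2^24, carry
handled with a cached byte plus a pending-0xFF run; the flush appends at
most 5 bytes plus pending bytes. Probabilities are quantised to integer
frequencies f = max(1, ⌊p·(2^14−4)⌋). With tot < 2^14 and range ≥ 2^24
the truncation loss is ≤ 2^-10 relative per symbol (~0.0014 bits), which
keeps the payload within 64 bits of the quantised ideal code length on
streams up to several thousand symbols. A 2^16 quantisation was
considered and rejected: with byte-wise renormalisation its worst-case
truncation loss breaks that bound. The sequence length lives in the
header, so no EOF symbol is coded; a truncated payload raises rather
than emitting wrong output.

### Container

`G3PY` magic, version, flags (referential/relative, feature-set
switches), learning rate (f32) + hidden nodes (u32), sequence length,
CRC-32 of the reference symbols (referential modes; a wrong reference
fails loudly instead of decoding garbage), the model spec strings, and
the payload. Model order A=0, C=1, G=2, T=3 is a format constant shared
by coder intervals and the symbol codec.

### Complexity profiles and storage cost

The profile is the per-position code length −log₂ q(x_n) *as charged by
the coder* (quantised probabilities), so the profile sum matches the
payload length within the coder's flush overhead. Smoothing is a centred
moving average (default window 512) with edge windows shortened to the
available positions. The storage-cost helper evaluates
processing time × power × energy price (s→h, W→kW) plus
copies × size × price-per-GB.

## Synthetic data

The generator emulates the structures the models exploit: an i.i.d.
uniform background, a source block re-planted in non-overlapping slots,
optional reverse-complemented copies, and per-base substitutions that
always change the base. It is a pure function of its spec (length,
block, copies, inverted fraction, substitution rate, seed). It does
*not* emulate GC bias, tandem/microsatellite structure, indels, or
long-range compositional drift of real genomes — so passing tests show
the machinery works on planted (inverted, substituted) repeats, not that
the measured ratios transfer to any particular genome.

Fixture sizes in the tests (60 kb repeat fixtures, a 100 kb heterogeneous
fixture of background / plain repeats / inverted repeats / two-letter
low-complexity segments) were chosen as the smallest scales at which the
mixing effects being asserted are clearly expressed.

## Design choices on open points

- Eq-style feature treatment of the blend pseudo-expert: it receives
  hit/best/bits like any model; its input vector is stretched from its
  probabilities.
- "Vote" is a strict maximum; partial ties (not full abstention) take
  the −0.1 branch.
- Reference models stay frozen during target coding, giving relative
  compression its cross-sequence meaning.
- Parameter-string field order is order:den:ir:budget:gamma with the
  tolerant fields after "/"; tolerance 0 disables the STCM.
- Presets: only published command strings are reproduced as named
  presets; numbered modes 1–5 are this package's own stacks.

## Known limitations

- Throughput is interpreter-bound (~5k symbols/s with a small stack);
  the design targets correctness and clarity, not the original tool's
  vectorised speed.
- Alphabet is strictly {A,C,G,T}; filtering other residues is left to
  upstream preprocessing.
- No FASTQ channels, multi-record containers or parallelism.
- Compression ratios on multi-gigabyte genomes are out of desk-scale
  test reach; the suite asserts the transferable contracts
  (losslessness, coder optimality, oracle equality, feature effects)
  instead.
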