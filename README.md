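# dnamix

Lossless DNA sequence compression by mixing finite-context models with an
online-trained neural network.

Genomic archives grow faster than storage does, and general-purpose
compressors waste most of a DNA sequence's structure: long approximate
repeats, reverse-complemented (inverted) repeats and regions whose local
statistics drift. `dnamix` is a reference-free and referential compressor
for sequences over {A, C, G, T}, aimed at people who need strong
compression ratios for archiving, or who use compression itself as an
analysis instrument (complexity profiles, cross-sequence similarity).

## The method

A bank of order-*k* Markov models (finite-context models, FCMs) predicts
each base from its left context with additive smoothing
p(s | c) = (n(c,s) + 1/d) / (Σ_m n(c,m) + 4/d).
Each model may mirror its updates at reverse-complement coordinates
(capturing inverted repeats) and may carry a substitution-tolerant
sub-model (STCM) that shares its counters but substitutes its own best
guess into a private context on a miss, tolerating up to *t* misses in a
recent history before resetting — cheap tolerance to point mutations
inside repeats. Models are described by the compact string
`order:den:ir:budget:gamma/tol:den:gamma`.

Two mixing stages turn the expert distributions into one coding
distribution:

1. **Soft-blending** — adaptive weights with a per-model forgetting factor
   γ: w_i ← w_i^γ · p_i(sym), floored and renormalised.
2. **Neural mixing** — a fully connected one-hidden-layer sigmoid network,
   trained online by SGD on squared error after every symbol. Its inputs
   are, per expert (the soft-blend itself is fed back as one more expert):
   the four stretched and centred probabilities
   stretch((1+f_j)/Σ(1+f_m)) − stretch(¼) with stretch(p) = ln(p/(1−p)),
   plus three performance trackers — *hit* (voting accuracy), *best*
   (best-of-all-models), *bits* (an EMA of normalised code length,
   α₁ = 0.15) — together with symbol frequencies over the last 8/16/64
   bases (12 nodes) and *nnbits*, the network's own code-length EMA
   (α₂ = 0.5). The normalised outputs drive a range coder.

Decompression replays the identical model/network trajectory, so the
container header only stores the model strings, sequence length and the
two network parameters (learning rate and hidden-node count, 8 bytes).

Referential modes: **relative** compression codes a target using only
models trained on a reference and frozen (a cross-sequence similarity
measure), **conditional** compression mixes frozen reference models with
target-adaptive ones.

## Worked example

```
$ dnamix synth -o fix.txt --length 20000 --block 1000 --repeats 12 \
      --inverted 0.5 --sub-rate 0.01 --seed 7
20000 bases written to fix.txt
$ dnamix compress -i fix.txt -o fix.dmx --tm 3:1:1:0:0.9/0:0:0 \
      --tm 11:16:1:0:0.95/2:16:0.95 --hidden 24 --lr 0.06
20000 bases -> 2568 bytes (1.0272 bits/base, 3.75s)
$ dnamix decompress -i fix.dmx -o fix.out.txt
20000 bases written to fix.out.txt
```

The fixture plants twelve copies of a 1 kb block (half of them
reverse-complemented, 1% substitutions) in 20 kb of random DNA. Random
DNA costs 2 bits/base; the planted structure pulls the whole file down to
1.03 bits/base, and decompression reproduces the input byte-exactly. The
storage-cost helper implements
Total = time×power×energy price + copies×size×price:

```
$ dnamix cost --time 3600 --power 34 --energy-price 0.12 \
      --copies 3 --size 1 --size-price 0.13
0.394080
```

i.e. one CPU-hour at 34 W and 0.12/kWh plus three stored copies of 1 GB
at 0.13/GB costs 0.394. `dnamix compress --profile out.tsv` additionally
writes the per-position complexity profile (−log₂ of the coded
probability, in bits).

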