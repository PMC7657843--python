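"""Symbol codec, FASTA/raw I/O and synthetic DNA fixtures.

Sequences are held as ``numpy.uint8`` arrays over the fixed alphabet
A=0, C=1, G=2, T=3.  The two-bit mapping determines the order of the
arithmetic coder's intervals, so it must be identical on the encoding
and decoding side; it is a constant of the file format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
ALPHABET_SIZE = 4

# byte -> symbol lookup; 255 marks an invalid residue
_ENC_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENC_LUT[ord(_c)] = _i
    _ENC_LUT[ord(_c.lower())] = _i

_DEC_LUT = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class AlphabetError(ValueError):
    """A residue outside {A,C,G,T} (case-insensitive) was encountered."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid residue {char!r} at position {position}; "
            f"alphabet is strictly {{A,C,G,T}}"
        )


class EmptyInputError(ValueError):
    """The input file contained no sequence data."""


class SynthSpecError(ValueError):
    """Inconsistent synthetic-fixture specification."""


def encode_symbols(text: str) -> np.ndarray:
    """Map an ACGT string (either case) to a uint8 symbol array.

    Raises :class:`AlphabetError` naming the first offending position.
    """
    if not text:
        return np.empty(0, dtype=np.uint8)
    raw = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
    syms = _ENC_LUT[raw]
    bad = np.nonzero(syms == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise AlphabetError(text[pos], pos)
    return syms


def decode_symbols(symbols: np.ndarray) -> str:
    """Inverse of :func:`encode_symbols`; emits uppercase ACGT."""
    symbols = np.asarray(symbols, dtype=np.uint8)
    return _DEC_LUT[symbols].tobytes().decode("ascii")


def reverse_complement(symbols: np.ndarray) -> np.ndarray:
    """Reverse complement under A<->T, C<->G (complement(s) = 3 - s)."""
    symbols = np.asarray(symbols, dtype=np.uint8)
    return (3 - symbols[::-1]).astype(np.uint8)


def read_fasta_filtered(path) -> np.ndarray:
    """Read a FASTA (headers dropped, records concatenated) or raw ACGT file.

    Whitespace is ignored, lowercase folded to uppercase; any other
    character is an :class:`AlphabetError` — residues are never silently
    dropped.  An empty file raises :class:`EmptyInputError`.
    """
    with open(path, "r") as fh:
        data = fh.read()
    stripped = data.lstrip()
    if not stripped:
        raise EmptyInputError(f"{path}: no sequence data")
    if stripped.startswith(">"):
        parts = [str(rec.seq) for rec in SeqIO.parse(io.StringIO(data), "fasta")]
        text = "".join(parts)
    else:
        text = "".join(data.split())
    if not text:
        raise EmptyInputError(f"{path}: no sequence data")
    return encode_symbols(text)


def write_raw(path, symbols: np.ndarray, line_width: int = 60) -> None:
    """Write a symbol array as plain ACGT text, wrapped at ``line_width``."""
    text = decode_symbols(symbols)
    with open(path, "w") as fh:
        for i in range(0, len(text), line_width):
            fh.write(text[i : i + line_width])
            fh.write("\n")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic DNA fixture with planted (inverted) repeats.

    A uniform i.i.d. background of ``length`` bases carries a source block
    (the first ``repeat_block_len`` bases) re-inserted ``n_repeats`` times
    in non-overlapping slots.  Each copy is reverse-complemented with
    probability ``inverted_fraction`` and every copied base is substituted
    by a different uniformly chosen symbol with probability
    ``substitution_rate``.  Generation is a pure function of the spec.
    """

    length: int
    repeat_block_len: int = 0
    n_repeats: int = 0
    inverted_fraction: float = 0.0
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.length < 0:
            raise SynthSpecError("length must be non-negative")
        if self.repeat_block_len < 0 or self.n_repeats < 0:
            raise SynthSpecError("repeat_block_len and n_repeats must be >= 0")
        for name in ("inverted_fraction", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthSpecError(f"{name} must lie in [0, 1]")
        if self.n_repeats and self.repeat_block_len:
            if self.repeat_block_len * (self.n_repeats + 1) > self.length:
                raise SynthSpecError(
                    "repeat blocks do not fit: "
                    f"{self.repeat_block_len} * ({self.n_repeats} + 1) "
                    f"> {self.length}"
                )


def generate_synthetic(spec: SynthSpec) -> np.ndarray:
    """Generate the fixture described by ``spec`` (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    seq = rng.integers(0, 4, size=spec.length, dtype=np.uint8)
    if spec.n_repeats == 0 or spec.repeat_block_len == 0:
        return seq
    blk_len = spec.repeat_block_len
    n_slots = spec.length // blk_len
    source = seq[:blk_len].copy()  # slot 0 holds the source block
    slots = rng.choice(np.arange(1, n_slots), size=spec.n_repeats, replace=False)
    for slot in slots:
        copy = source.copy()
        if rng.random() < spec.inverted_fraction:
            copy = reverse_complement(copy)
        mask = rng.random(blk_len) < spec.substitution_rate
        n_sub = int(mask.sum())
        if n_sub:
            # adding 1..3 mod 4 always yields a *different* symbol
            copy[mask] = (copy[mask] + rng.integers(1, 4, size=n_sub)) % 4
        seq[slot * blk_len : (slot + 1) * blk_len] = copy
    return seq
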