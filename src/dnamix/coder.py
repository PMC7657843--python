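"""Range coder over a 4-symbol alphabet driven by probability vectors.

A 32-bit range coder with byte-wise renormalisation and carry handling
via a cached byte plus a pending-0xFF run.  Probabilities are quantised
to integer frequencies summing below 2^14 with a floor of one count per
symbol, so the coder never sees a zero-width interval; renormalisation
keeps range >= 2^24, bounding the truncation loss per symbol to about
2^-10 of a bit.  Encoder and decoder are an exact inverse pair given the
same probability stream.
"""

from __future__ import annotations

import numpy as np

TOTAL_BITS = 14
_SCALE = (1 << TOTAL_BITS) - 4
_TOP = 1 << 24
_MASK32 = 0xFFFFFFFF


class CoderError(RuntimeError):
    pass


class TruncatedStreamError(CoderError):
    """The decoder ran past the end of the payload."""


def quantize(probs: np.ndarray) -> np.ndarray:
    """Integer frequencies for a probability 4-vector (floor 1 per symbol)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (4,) or not np.all(probs > 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise CoderError("invalid probability vector")
    f = (probs * _SCALE).astype(np.int64)
    np.maximum(f, 1, out=f)
    return f


def quantized_bits(probs: np.ndarray, sym: int) -> float:
    """Code length -log2(q(sym)) charged by the coder for this symbol."""
    f = quantize(probs)
    return float(-np.log2(f[sym] / f.sum()))


class RangeEncoder:
    def __init__(self):
        self._low = 0
        self._range = _MASK32
        self._cache = 0
        self._pending = 0
        self._started = False
        self._out = bytearray()
        self._finalized = False

    def _shift_low(self):
        low = self._low
        if low < 0xFF000000 or low > _MASK32:
            carry = low >> 32
            if self._started:
                self._out.append((self._cache + carry) & 0xFF)
            else:
                # the coded number is < 2^32, so the virtual leading byte
                # is always 0; emit it so the decoder priming is uniform
                self._out.append(carry & 0xFF)
                self._started = True
            while self._pending:
                self._out.append((0xFF + carry) & 0xFF)
                self._pending -= 1
            self._cache = (low >> 24) & 0xFF
            self._started = True
        else:
            self._pending += 1
        self._low = (low << 8) & _MASK32

    def encode_symbol(self, probs: np.ndarray, sym: int):
        if self._finalized:
            raise CoderError("encoder already finalized")
        freqs = quantize(probs)
        tot = int(freqs.sum())
        cum = int(freqs[:sym].sum())
        r = self._range // tot
        self._low += r * cum
        self._range = r * int(freqs[sym])
        while self._range < _TOP:
            self._range <<= 8
            self._shift_low()

    def finalize(self) -> bytes:
        if self._finalized:
            raise CoderError("finalize called twice")
        for _ in range(5):
            self._shift_low()
        # unresolved carry-watch bytes: no carry can arrive any more
        self._out.extend(b"\xff" * self._pending)
        self._pending = 0
        self._finalized = True
        return bytes(self._out)


class RangeDecoder:
    def __init__(self, payload: bytes):
        self._data = payload
        self._pos = 0
        self._range = _MASK32
        self._code = 0
        for _ in range(5):
            self._code = (self._code << 8) | self._next_byte()

    def _next_byte(self) -> int:
        if self._pos >= len(self._data):
            raise TruncatedStreamError("compressed payload exhausted")
        b = self._data[self._pos]
        self._pos += 1
        return b

    def decode_symbol(self, probs: np.ndarray) -> int:
        freqs = quantize(probs)
        tot = int(freqs.sum())
        r = self._range // tot
        v = min(self._code // r, tot - 1)
        cum = np.cumsum(freqs)
        sym = int(np.searchsorted(cum, v, side="right"))
        cum_low = int(cum[sym - 1]) if sym else 0
        self._code -= r * cum_low
        self._range = r * int(freqs[sym])
        while self._range < _TOP:
            self._code = (self._code << 8) | self._next_byte()
            self._range <<= 8
        return sym
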