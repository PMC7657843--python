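"""Inputs derived for the neural mixer.

Covers the stretched/centred model probabilities, the per-model
performance trackers hit/best/bits, the mixer's own nnbits moving
average, and the last-8/16/64 symbol-frequency features.
"""

from __future__ import annotations

import math

import numpy as np

EPS_P = 1e-6
HIT_STEP = 0.1
ALPHA_BITS = 0.15  # EMA rate for per-model bits
ALPHA_NNBITS = 0.5  # EMA rate for the network's own bits
MEAN_P = 0.25  # mean symbol probability assumed for DNA
WINDOW_SIZES = (8, 16, 64)

_STRETCH_MEAN = math.log(MEAN_P / (1.0 - MEAN_P))  # stretch(0.25) = ln(1/3)


def stretch(p):
    """Logit transform ln(p/(1-p)), clamped away from 0 and 1.

    Magnifies probabilities near the extremes before they enter the
    mixer; antisymmetric about p = 0.5.
    """
    p = np.clip(p, EPS_P, 1.0 - EPS_P)
    return np.log(p / (1.0 - p))


def model_input_vector(counts: np.ndarray) -> np.ndarray:
    """Stretched, centred distribution from a model's 4 context counters.

    Uses the +1-smoothed frequencies (1+f_j)/sum_m(1+f_m); subtracting
    stretch(0.25) centres the all-uniform case at exactly zero.
    """
    f = 1.0 + np.asarray(counts, dtype=np.float64)
    return stretch(f / f.sum()) - _STRETCH_MEAN


def prob_input_vector(p: np.ndarray) -> np.ndarray:
    """Stretched, centred input for an expert given directly as a
    distribution (the soft-blend pseudo-model has no counters)."""
    return stretch(p) - _STRETCH_MEAN


def _clip_unit(x: np.ndarray) -> None:
    np.clip(x, -1.0, 1.0, out=x)


def update_hit(hit_prev: float, probs: np.ndarray, sym: int) -> float:
    """Voting-accuracy tracker: +0.1 on a strict correct top vote, -0.1
    otherwise, unchanged when the model abstains (all symbols equal)."""
    probs = np.asarray(probs)
    if np.all(probs == probs[0]):
        return hit_prev
    p_sym = probs[sym]
    others = np.delete(probs, sym)
    if p_sym > others.max():
        new = hit_prev + HIT_STEP
    else:
        new = hit_prev - HIT_STEP
    return min(1.0, max(-1.0, new))


def update_best(best_prev: np.ndarray, probs_all: np.ndarray, sym: int) -> np.ndarray:
    """Best-of-all-models tracker, one entry per model.

    A model gains 0.1 when its probability for the true symbol is >= every
    other model's (abstainers stay in the comparison set but cannot win),
    loses 0.1 otherwise, and abstaining models are left unchanged.
    """
    probs_all = np.asarray(probs_all, dtype=np.float64)
    best = np.asarray(best_prev, dtype=np.float64).copy()
    p_sym = probs_all[:, sym]
    abstain = np.all(probs_all == probs_all[:, :1], axis=1)
    top = p_sym.max()
    win = (p_sym >= top) & ~abstain
    active = ~abstain
    best[active & win] += HIT_STEP
    best[active & ~win] -= HIT_STEP
    _clip_unit(best)
    return best


def update_bits(
    bits_prev: float, p_sym: float, alpha: float = ALPHA_BITS, mean_p: float = MEAN_P
) -> float:
    """EMA of a model's normalised code length:
    alpha*(-log2 p_sym + log2 mean_p) + (1-alpha)*bits_prev."""
    return alpha * (-math.log2(p_sym) + math.log2(mean_p)) + (1.0 - alpha) * bits_prev


def update_nnbits(
    nnbits_prev: float, p_sym: float, alpha: float = ALPHA_NNBITS, mean_p: float = MEAN_P
) -> float:
    """Same EMA for the network's own output probability, alpha = 0.5."""
    return update_bits(nnbits_prev, p_sym, alpha=alpha, mean_p=mean_p)


class PerformanceState:
    """hit/best/bits per expert (including the blend pseudo-model)."""

    def __init__(self, n_experts: int):
        self.hit = np.zeros(n_experts)
        self.best = np.zeros(n_experts)
        self.bits = np.zeros(n_experts)

    def update(self, probs_all: np.ndarray, sym: int) -> None:
        probs_all = np.asarray(probs_all, dtype=np.float64)
        p_sym = probs_all[:, sym]
        abstain = np.all(probs_all == probs_all[:, :1], axis=1)

        # hit: strict top vote on the true symbol
        rest = probs_all.copy()
        rest[np.arange(rest.shape[0]), sym] = -np.inf
        strict_top = p_sym > rest.max(axis=1)
        self.hit = np.where(abstain, self.hit, np.where(strict_top, self.hit + HIT_STEP, self.hit - HIT_STEP))
        _clip_unit(self.hit)

        # best: >= every model's probability of the true symbol
        top = p_sym.max()
        win = (p_sym >= top) & ~abstain
        self.best = np.where(abstain, self.best, np.where(win, self.best + HIT_STEP, self.best - HIT_STEP))
        _clip_unit(self.best)

        # bits: per-model EMA of normalised code length
        self.bits = ALPHA_BITS * (-np.log2(np.maximum(p_sym, EPS_P)) + math.log2(MEAN_P)) + (
            1.0 - ALPHA_BITS
        ) * self.bits


class RecentWindow:
    """Ring buffer of the last 64 symbols with per-window symbol counts."""

    def __init__(self):
        self._buf = np.zeros(64, dtype=np.uint8)
        self._n = 0
        self._counts = {w: np.zeros(4, dtype=np.int64) for w in WINDOW_SIZES}

    def push(self, sym: int) -> None:
        for w, c in self._counts.items():
            if self._n >= w:
                c[self._buf[(self._n - w) % 64]] -= 1
            c[sym] += 1
        self._buf[self._n % 64] = sym
        self._n += 1

    def features(self) -> np.ndarray:
        """12 values: per window size, symbol frequencies affinely scaled
        to [-1, 1] (2f - 1); zero (neutral) before the first symbol."""
        out = np.empty(12)
        for i, w in enumerate(WINDOW_SIZES):
            eff = min(self._n, w)
            if eff == 0:
                out[4 * i : 4 * i + 4] = 0.0
            else:
                out[4 * i : 4 * i + 4] = 2.0 * (self._counts[w] / eff) - 1.0
        return out

    def frequencies(self, window: int) -> np.ndarray:
        """Unscaled symbol frequencies over the trailing ``window`` symbols."""
        eff = min(self._n, window)
        if eff == 0:
            return np.full(4, 0.25)
        return self._counts[window] / eff
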