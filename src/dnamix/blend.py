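"""Adaptive soft-blending of expert probabilities.

A convex combination of the experts' 4-symbol distributions whose
weights decay with a per-expert forgetting factor gamma and multiply by
each expert's probability of the observed symbol:

    w_i <- w_i^gamma_i * p_i(sym),   then floor and renormalise.

The blended distribution is both a usable coder input on its own and one
of the neural mixer's inputs (the mixer treats it as one more expert).
"""

from __future__ import annotations

import numpy as np

WEIGHT_FLOOR = 1e-8


class SoftBlend:
    def __init__(self, gammas, weight_floor: float = WEIGHT_FLOOR):
        self.gammas = np.asarray(gammas, dtype=np.float64)
        if self.gammas.ndim != 1 or self.gammas.size == 0:
            raise ValueError("need one gamma per expert")
        n = self.gammas.size
        self.weights = np.full(n, 1.0 / n)
        self.weight_floor = weight_floor

    @property
    def n_experts(self) -> int:
        return self.gammas.size

    def predict(self, probs: np.ndarray) -> np.ndarray:
        """Weighted mixture of per-expert distributions, renormalised.

        ``probs`` is an (n_experts, 4) array, one distribution per row.
        """
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape[0] != self.n_experts:
            raise ValueError(
                f"expected {self.n_experts} expert distributions, got {probs.shape[0]}"
            )
        mixed = self.weights @ probs
        return mixed / mixed.sum()

    def update(self, probs: np.ndarray, sym: int) -> None:
        w = self.weights**self.gammas * probs[:, sym]
        np.maximum(w, self.weight_floor, out=w)
        self.weights = w / w.sum()
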