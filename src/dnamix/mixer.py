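"""One-hidden-layer sigmoid network that mixes the experts online.

The network is trained with plain stochastic gradient descent on the
squared error between its raw sigmoid outputs and the one-hot encoding
of each symbol, one step per coded symbol, for the whole sequence.  Its
normalised outputs drive the arithmetic coder, so the forward pass must
be bit-reproducible between compression and decompression: the weight
initialisation seed is a fixed constant of the format and only the
learning rate and hidden-node count travel in the container header.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

EPS_P = 1e-6
DEFAULT_LEARNING_RATE = 0.03
DEFAULT_HIDDEN_NODES = 64
NET_SEED = 0x5EC0DE  # fixed format constant, not stored in the header

N_WINDOW_FEATURES = 12
FEATURES_PER_EXPERT = 7  # 4 stretched probabilities + hit + best + bits


def n_network_inputs(n_experts: int, derived: bool = True) -> int:
    """Input-layer width for ``n_experts`` experts (soft-blend included by
    the caller): 4 (+3 derived) nodes per expert, 12 window nodes, 1 nnbits."""
    per = 4 + (3 if derived else 0)
    return per * n_experts + N_WINDOW_FEATURES + 1


def assemble_inputs(model_vectors, perf=None, window_features=None, nnbits=0.0) -> np.ndarray:
    """Concatenate the mixer input vector in its fixed layout:

    [expert 1..E stretched 4-vectors | hit_1..E | best_1..E | bits_1..E |
     12 window frequencies | nnbits]

    ``perf`` is a (hit, best, bits) triple of length-E arrays or None when
    the derived features are disabled.
    """
    parts = list(model_vectors)
    n = len(parts)
    if perf is not None:
        hit, best, bits = perf
        if not (len(hit) == len(best) == len(bits) == n):
            raise ValueError("performance features must match the expert count")
        parts += [hit, best, bits]
    if window_features is None:
        window_features = np.zeros(N_WINDOW_FEATURES)
    if len(window_features) != N_WINDOW_FEATURES:
        raise ValueError(f"expected {N_WINDOW_FEATURES} window features")
    parts.append(window_features)
    parts.append([nnbits])
    return np.concatenate([np.asarray(p, dtype=np.float64).ravel() for p in parts])


def xavier_uniform(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class MixerNetwork:
    """Fully connected 1-hidden-layer sigmoid mixer with bias nodes on the
    input and hidden layers, Xavier-initialised."""

    def __init__(
        self,
        n_inputs: int,
        n_hidden: int = DEFAULT_HIDDEN_NODES,
        learning_rate: float = DEFAULT_LEARNING_RATE,
        seed: int = NET_SEED,
    ):
        if n_hidden < 1:
            raise ValueError("need at least one hidden node")
        self.n_inputs = n_inputs
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        rng = np.random.default_rng(seed)
        self.w_ih = xavier_uniform(rng, n_hidden, n_inputs + 1)
        self.w_ho = xavier_uniform(rng, 4, n_hidden + 1)
        self._xb = np.empty(n_inputs + 1)
        self._hb = np.empty(n_hidden + 1)
        self._raw = None

    def forward(self, x: np.ndarray):
        """Return (raw sigmoid outputs, coding distribution).

        The coding distribution is the raw outputs floored at EPS_P and
        divided by their sum; unlike a convex blend it can leave the hull
        of the expert distributions.
        """
        if len(x) != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {len(x)}")
        self._xb[:-1] = x
        self._xb[-1] = 1.0
        self._hb[:-1] = expit(self.w_ih @ self._xb)
        self._hb[-1] = 1.0
        raw = expit(self.w_ho @ self._hb)
        self._raw = raw
        coded = np.maximum(raw, EPS_P)
        return raw, coded / coded.sum()

    def train_step(self, x: np.ndarray, sym: int) -> None:
        """One SGD step on L = 1/2 * sum((raw - onehot)^2), taken on the
        raw sigmoid outputs (pre-normalisation)."""
        raw = self._raw
        if raw is None or not np.array_equal(self._xb[:-1], x):
            _, _ = self.forward(x)
            raw = self._raw
        target = np.zeros(4)
        target[sym] = 1.0
        d_out = (raw - target) * raw * (1.0 - raw)
        h = self._hb[:-1]
        d_hidden = (self.w_ho[:, :-1].T @ d_out) * h * (1.0 - h)
        lr = self.learning_rate
        self.w_ho -= lr * np.outer(d_out, self._hb)
        self.w_ih -= lr * np.outer(d_hidden, self._xb)
        self._raw = None
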