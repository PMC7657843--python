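"""Finite-context models and substitution-tolerant context models.

An order-k FCM predicts the next base from bounded (context, symbol)
counters with additive smoothing alpha = 1/alpha_den.  With the
inverted-repeat flag set, every update is mirrored at the
reverse-complement coordinates, so a single pass over a sequence also
learns its reverse complement.  A substitution-tolerant context model
(STCM) shares the FCM's counters but maintains a *private* context into
which it substitutes its own prediction on a miss, tolerating up to
``tolerance`` misses in a sliding history before resetting to the true
context.  Models flagged ``is_reference`` are trained on a reference
sequence and frozen while the target is coded.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

COUNTER_CAP = 65535  # 16-bit counters, halve-all-on-cap
DENSE_CONTEXT_LIMIT = 1 << 24  # dense backing iff 4^k <= 2^24
_HASH_CELL_UNIT = 1 << 16
_HASH_CELL_MAX = 1 << 22
_PROBE_LIMIT = 16
_MIX = 0x9E3779B97F4A7C15  # splitmix64 multiplier


@dataclass
class ModelConfig:
    """Parameters of one context model (and its optional tolerant sub-model).

    Mirrors the ``order:alpha_den:ir:budget:gamma/tol:tol_alpha_den:tol_gamma``
    command-string convention.
    """

    order: int
    alpha_den: int = 1
    ir: bool = True
    store_budget: int = 0
    gamma: float = 0.9
    tolerance: int = 0
    tol_alpha_den: int = 1
    tol_gamma: float = 0.9
    is_reference: bool = False

    def __post_init__(self):
        if not 1 <= self.order <= 24:
            raise ValueError(f"order must be in 1..24, got {self.order}")
        if self.alpha_den < 1 or self.tol_alpha_den < 1:
            raise ValueError("alpha denominators must be >= 1")
        for g in (self.gamma, self.tol_gamma):
            if not 0.0 <= g < 1.0:
                raise ValueError(f"forgetting factor must be in [0, 1), got {g}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    def spec_string(self) -> str:
        def num(x: float) -> str:
            return f"{x:g}"

        return (
            f"{self.order}:{self.alpha_den}:{int(self.ir)}:{self.store_budget}:"
            f"{num(self.gamma)}/{self.tolerance}:{self.tol_alpha_den}:"
            f"{num(self.tol_gamma)}"
        )


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1)).bit_length()


class CountStore:
    """Per-context 4-way counters, dense for small orders, hashed above.

    The hashed backing uses open addressing with linear probing and the
    full context as the stored fingerprint; after ``_PROBE_LIMIT`` probes a
    collision overwrites the first probed cell, keeping RAM constant.
    """

    def __init__(self, order: int, store_budget: int = 0):
        self.order = order
        n_contexts = 4**order
        self.dense = n_contexts <= DENSE_CONTEXT_LIMIT
        if self.dense:
            self._counts = np.zeros((n_contexts, 4), dtype=np.uint16)
        else:
            cells = _next_pow2(max(store_budget, 1) * _HASH_CELL_UNIT)
            cells = min(cells, _HASH_CELL_MAX)
            self._mask = cells - 1
            self._keys = np.full(cells, -1, dtype=np.int64)
            self._counts = np.zeros((cells, 4), dtype=np.uint16)
        self.frozen = False

    def _slot(self, ctx: int, create: bool) -> int:
        h = ((ctx * _MIX) & 0xFFFFFFFFFFFFFFFF) >> 40
        idx = h & self._mask
        keys = self._keys
        first = idx
        for _ in range(_PROBE_LIMIT):
            k = keys[idx]
            if k == ctx:
                return idx
            if k == -1:
                if create:
                    keys[idx] = ctx
                    return idx
                return -1
            idx = (idx + 1) & self._mask
        if create:  # collision: evict the home slot
            keys[first] = ctx
            self._counts[first] = 0
            return first
        return -1

    def counts(self, ctx: int) -> np.ndarray:
        """Return the 4 counters for ``ctx`` (a copy-safe read view)."""
        if self.dense:
            return self._counts[ctx]
        idx = self._slot(ctx, create=False)
        if idx < 0:
            return _ZERO4
        return self._counts[idx]

    def increment(self, ctx: int, sym: int) -> None:
        if self.frozen:
            return
        if self.dense:
            row = self._counts[ctx]
        else:
            row = self._counts[self._slot(ctx, create=True)]
        if row.max() >= COUNTER_CAP:
            row >>= 1
        row[sym] += 1


_ZERO4 = np.zeros(4, dtype=np.uint16)
_UNIFORM = np.full(4, 0.25)


def fcm_probability(store: CountStore, ctx: int, alpha_den: int) -> np.ndarray:
    """p(s) = (c(ctx,s) + a) / (sum_m c(ctx,m) + 4a) with a = 1/alpha_den."""
    c = store.counts(ctx)
    alpha = 1.0 / alpha_den
    p = c + alpha
    return p / p.sum()


class FCM:
    """Order-k finite-context model run position by position.

    ``probabilities()`` predicts the next symbol; ``update(sym)`` then
    feeds it the symbol that actually occurred.  During the first k
    positions the model abstains (exact uniform) and performs no update.
    """

    def __init__(self, cfg: ModelConfig, store: CountStore | None = None):
        self.cfg = cfg
        self.k = cfg.order
        self.store = store if store is not None else CountStore(cfg.order, cfg.store_budget)
        self._ctx_mask = 4**self.k - 1
        self._ir_shift = 2 * (self.k - 1)
        self.reset_position()

    def reset_position(self) -> None:
        """Forget positional state (context history), keep the counters."""
        self.ctx = 0
        self.irc = 0
        self.n = 0
        self._buf = deque(maxlen=self.k)

    @property
    def gamma(self) -> float:
        return self.cfg.gamma

    def probabilities(self) -> np.ndarray:
        if self.n < self.k:
            return _UNIFORM
        return fcm_probability(self.store, self.ctx, self.cfg.alpha_den)

    def input_counts(self) -> np.ndarray:
        """Counters at the current context (zero during warm-up)."""
        if self.n < self.k:
            return _ZERO4
        return self.store.counts(self.ctx)

    def update(self, sym: int) -> None:
        full = self.n >= self.k
        if full and not self.store.frozen:
            self.store.increment(self.ctx, sym)
        new_irc = (self.irc >> 2) | ((3 - sym) << self._ir_shift)
        if full and self.cfg.ir and not self.store.frozen:
            # mirrored update: context = revcomp of the k symbols ending
            # here, symbol = complement of the symbol k positions back
            self.store.increment(new_irc, 3 - self._buf[0])
        self.irc = new_irc
        self.ctx = ((self.ctx << 2) | sym) & self._ctx_mask
        self._buf.append(sym)
        self.n += 1


class STCM:
    """Substitution-tolerant context model sharing an FCM's counters.

    Emits the shared store's distribution at its private context.  After
    the true symbol is known: a correct top-vote extends the private
    context with the truth, a miss extends it with the model's own guess
    (the assumed substitution).  More than ``tolerance`` misses inside the
    recent hit/miss history reset the private context to the true trailing
    k symbols and clear the history.
    """

    def __init__(self, cfg: ModelConfig, store: CountStore):
        if cfg.tolerance < 1:
            raise ValueError("STCM requires tolerance >= 1")
        self.cfg = cfg
        self.k = cfg.order
        self.store = store
        self._ctx_mask = 4**self.k - 1
        self.history_capacity = max(2 * cfg.tolerance, 8)
        self.reset_position()

    def reset_position(self) -> None:
        self.pctx = 0
        self.true_ctx = 0
        self.n = 0
        self.history: deque = deque()
        self.miss_count = 0

    @property
    def gamma(self) -> float:
        return self.cfg.tol_gamma

    def probabilities(self) -> np.ndarray:
        if self.n < self.k:
            return _UNIFORM
        return fcm_probability(self.store, self.pctx, self.cfg.tol_alpha_den)

    def input_counts(self) -> np.ndarray:
        if self.n < self.k:
            return _ZERO4
        return self.store.counts(self.pctx)

    def update(self, sym: int) -> None:
        self.true_ctx = ((self.true_ctx << 2) | sym) & self._ctx_mask
        if self.n >= self.k:
            pred = int(np.argmax(self.store.counts(self.pctx)))
            hit = pred == sym
            self.history.append(hit)
            if not hit:
                self.miss_count += 1
            if len(self.history) > self.history_capacity:
                old = self.history.popleft()
                if not old:
                    self.miss_count -= 1
            if self.miss_count > self.cfg.tolerance:
                self.pctx = self.true_ctx
                self.history.clear()
                self.miss_count = 0
            else:
                ext = sym if hit else pred
                self.pctx = ((self.pctx << 2) | ext) & self._ctx_mask
        else:
            self.pctx = self.true_ctx
        self.n += 1


def build_experts(cfg: ModelConfig) -> list:
    """Expert predictors for one config: the FCM, plus an STCM if tolerant."""
    fcm = FCM(cfg)
    experts = [fcm]
    if cfg.tolerance > 0:
        experts.append(STCM(cfg, fcm.store))
    return experts


def train_on_reference(experts: list, ref: np.ndarray) -> None:
    """One full FCM pass over ``ref``; freezes the stores and resets
    positional state so target coding starts from a clean context."""
    if len(ref) == 0:
        raise ValueError("reference sequence is empty")
    fcms = [e for e in experts if isinstance(e, FCM)]
    for fcm in fcms:
        for sym in ref:
            fcm.update(int(sym))
        fcm.store.frozen = True
    for e in experts:
        e.reset_position()
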