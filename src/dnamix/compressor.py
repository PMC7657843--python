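"""Per-symbol compression pipeline, container format and utilities.

For every symbol the engine gathers expert distributions (context
models, tolerant context models and, in referential modes, frozen
reference-trained models), soft-blends them, assembles the mixer input
vector, takes the network's normalised output as the coding
distribution, codes the symbol, and then updates counters (target models
only), blend weights, performance features, window counts, nnbits and
the network weights.  Decompression replays the identical state
trajectory, so the container header only needs the model specification
strings, the sequence length and the two network parameters (learning
rate and hidden-node count, 8 bytes).
"""

from __future__ import annotations

import math
import struct
import zlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from . import features as ft
from .blend import SoftBlend
from .coder import RangeDecoder, RangeEncoder, quantized_bits
from .mixer import (
    DEFAULT_HIDDEN_NODES,
    DEFAULT_LEARNING_RATE,
    MixerNetwork,
    NET_SEED,
    assemble_inputs,
    n_network_inputs,
)
from .models import ModelConfig, build_experts, train_on_reference

MAGIC = b"G3PY"
FORMAT_VERSION = 1

_FLAG_HAS_REFERENCE = 1
_FLAG_RELATIVE = 2
_FLAG_NO_BLEND_INPUT = 4
_FLAG_NO_DERIVED = 8


class FormatError(ValueError):
    """Malformed or incompatible container."""


class ModelSpecError(ValueError):
    """Malformed model parameter string."""


def parse_model_spec(spec: str, is_reference: bool = False) -> ModelConfig:
    """Parse ``order:alpha_den:ir:budget:gamma/tol:tol_alpha_den:tol_gamma``.

    ``/0:0:0`` disables the tolerant sub-model.
    """
    parts = spec.strip().split("/")
    if len(parts) != 2:
        raise ModelSpecError(f"{spec!r}: expected one '/' separating FCM and STCM fields")
    head = parts[0].split(":")
    tail = parts[1].split(":")
    if len(head) != 5:
        raise ModelSpecError(f"{spec!r}: expected 5 ':'-separated FCM fields, got {len(head)}")
    if len(tail) != 3:
        raise ModelSpecError(f"{spec!r}: expected 3 ':'-separated STCM fields, got {len(tail)}")
    fields = head + tail
    names = ["order", "alpha_den", "ir", "store_budget", "gamma",
             "tolerance", "tol_alpha_den", "tol_gamma"]
    vals = {}
    for i, (name, raw) in enumerate(zip(names, fields)):
        try:
            vals[name] = float(raw) if name in ("gamma", "tol_gamma") else int(raw)
        except ValueError as exc:
            raise ModelSpecError(f"{spec!r}: field {i} ({name}) is not numeric") from exc
    tol = vals["tolerance"]
    try:
        return ModelConfig(
            order=vals["order"],
            alpha_den=vals["alpha_den"],
            ir=bool(vals["ir"]),
            store_budget=vals["store_budget"],
            gamma=vals["gamma"],
            tolerance=tol,
            tol_alpha_den=max(vals["tol_alpha_den"], 1),
            tol_gamma=vals["tol_gamma"] if tol else vals["gamma"],
            is_reference=is_reference,
        )
    except ValueError as exc:
        raise ModelSpecError(f"{spec!r}: {exc}") from exc


def load_presets() -> dict:
    """Named model-stack presets shipped with the package."""
    text = resources.files("dnamix").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_configs(name: str) -> list[ModelConfig]:
    presets = load_presets()
    key = str(name)
    if key not in presets:
        raise ModelSpecError(f"unknown preset {name!r}; available: {sorted(presets)}")
    entry = presets[key]
    target = [parse_model_spec(s) for s in entry.get("tm", [])]
    ref = [parse_model_spec(s, is_reference=True) for s in entry.get("rm", [])]
    return target + ref


class CompressorEngine:
    """Deterministic per-symbol pipeline shared by encoder and decoder."""

    def __init__(
        self,
        configs: list[ModelConfig],
        learning_rate: float = DEFAULT_LEARNING_RATE,
        hidden_nodes: int = DEFAULT_HIDDEN_NODES,
        reference: np.ndarray | None = None,
        include_blend: bool = True,
        include_derived: bool = True,
    ):
        if not configs:
            raise ValueError("need at least one model")
        ref_cfgs = [c for c in configs if c.is_reference]
        if ref_cfgs and reference is None:
            raise ValueError("reference models given but no reference sequence")
        self.configs = list(configs)
        self.experts = []
        for cfg in configs:
            group = build_experts(cfg)
            if cfg.is_reference:
                train_on_reference(group, reference)
            self.experts.extend(group)
        self.n_experts = len(self.experts)
        self.include_blend = include_blend
        self.include_derived = include_derived
        self.blend = SoftBlend([e.gamma for e in self.experts])
        n_inputs_experts = self.n_experts + (1 if include_blend else 0)
        self.perf = ft.PerformanceState(n_inputs_experts)
        self.window = ft.RecentWindow()
        self.nnbits = 0.0
        self.net = MixerNetwork(
            n_network_inputs(n_inputs_experts, derived=include_derived),
            n_hidden=hidden_nodes,
            learning_rate=learning_rate,
            seed=NET_SEED,
        )

    def predict(self):
        """Expert distributions, blend, mixer input and coding distribution."""
        probs = np.empty((self.n_experts, 4))
        vectors = []
        for i, e in enumerate(self.experts):
            probs[i] = e.probabilities()
            vectors.append(ft.model_input_vector(e.input_counts()))
        blend_p = self.blend.predict(probs)
        if self.include_blend:
            vectors.append(ft.prob_input_vector(blend_p))
        perf = (
            (self.perf.hit, self.perf.best, self.perf.bits)
            if self.include_derived
            else None
        )
        x = assemble_inputs(vectors, perf, self.window.features(), self.nnbits)
        _, coded = self.net.forward(x)
        return probs, blend_p, x, coded

    def observe(self, sym: int, probs, blend_p, x, coded) -> None:
        """Advance every adaptive component with the symbol that occurred."""
        if self.include_blend:
            all_probs = np.vstack([probs, blend_p])
        else:
            all_probs = probs
        self.perf.update(all_probs, sym)
        self.nnbits = ft.update_nnbits(self.nnbits, max(float(coded[sym]), ft.EPS_P))
        self.blend.update(probs, sym)
        self.window.push(sym)
        for e in self.experts:
            e.update(sym)
        self.net.train_step(x, sym)


@dataclass(frozen=True)
class ContainerInfo:
    """Decoded container header."""

    configs: list
    seq_len: int
    learning_rate: float
    hidden_nodes: int
    relative: bool
    has_reference: bool
    include_blend: bool
    include_derived: bool
    ref_crc: int
    payload: bytes


def _build_configs(target_specs, ref_specs, disable_ir):
    configs = [parse_model_spec(s) for s in target_specs or []]
    configs += [parse_model_spec(s, is_reference=True) for s in ref_specs or []]
    if disable_ir:
        for c in configs:
            c.ir = False
    return configs


def compress(
    seq: np.ndarray,
    target_specs=None,
    ref_specs=None,
    *,
    mode: str | None = None,
    reference: np.ndarray | None = None,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    hidden_nodes: int = DEFAULT_HIDDEN_NODES,
    disable_ir: bool = False,
    include_blend: bool = True,
    include_derived: bool = True,
) -> bytes:
    """Compress a symbol sequence into a self-describing container.

    Reference-free: give ``target_specs`` (or ``mode``).  Relative: only
    ``ref_specs`` plus ``reference``.  Conditional (hybrid): both kinds.
    """
    if mode is not None:
        configs = preset_configs(mode)
        if disable_ir:
            for c in configs:
                c.ir = False
    else:
        configs = _build_configs(target_specs, ref_specs, disable_ir)
    if not configs:
        raise ValueError("no models configured")
    ref_cfgs = [c for c in configs if c.is_reference]
    relative = bool(ref_cfgs) and len(ref_cfgs) == len(configs)
    if ref_cfgs and reference is None:
        raise ValueError("referential mode requires a reference sequence")

    # the header carries the learning rate as a 32-bit float; train with
    # exactly the value the decompressor will read back
    learning_rate = float(np.float32(learning_rate))

    engine = CompressorEngine(
        configs,
        learning_rate=learning_rate,
        hidden_nodes=hidden_nodes,
        reference=reference,
        include_blend=include_blend,
        include_derived=include_derived,
    )
    enc = RangeEncoder()
    seq = np.asarray(seq, dtype=np.uint8)
    for sym in seq:
        sym = int(sym)
        probs, blend_p, x, coded = engine.predict()
        enc.encode_symbol(coded, sym)
        engine.observe(sym, probs, blend_p, x, coded)
    payload = enc.finalize() if len(seq) else b""

    flags = 0
    if ref_cfgs:
        flags |= _FLAG_HAS_REFERENCE
    if relative:
        flags |= _FLAG_RELATIVE
    if not include_blend:
        flags |= _FLAG_NO_BLEND_INPUT
    if not include_derived:
        flags |= _FLAG_NO_DERIVED
    ref_crc = zlib.crc32(np.asarray(reference, dtype=np.uint8).tobytes()) if ref_cfgs else 0

    out = bytearray()
    out += MAGIC
    out.append(FORMAT_VERSION)
    out.append(flags)
    # the two network parameters, 8 bytes total
    out += struct.pack("<fI", learning_rate, hidden_nodes)
    out += struct.pack("<QIH", len(seq), ref_crc, len(configs))
    for cfg in configs:
        s = cfg.spec_string().encode("ascii")
        out += struct.pack("<BH", int(cfg.is_reference), len(s))
        out += s
    out += struct.pack("<Q", len(payload))
    out += payload
    return bytes(out)


def read_header(container: bytes) -> ContainerInfo:
    try:
        if container[:4] != MAGIC:
            raise FormatError("bad magic bytes")
        version, flags = container[4], container[5]
        if version != FORMAT_VERSION:
            raise FormatError(f"unsupported format version {version}")
        off = 6
        learning_rate, hidden_nodes = struct.unpack_from("<fI", container, off)
        off += 8
        seq_len, ref_crc, n_cfg = struct.unpack_from("<QIH", container, off)
        off += 14
        configs = []
        for _ in range(n_cfg):
            is_ref, slen = struct.unpack_from("<BH", container, off)
            off += 3
            spec = container[off : off + slen].decode("ascii")
            off += slen
            configs.append(parse_model_spec(spec, is_reference=bool(is_ref)))
        (payload_len,) = struct.unpack_from("<Q", container, off)
        off += 8
        payload = container[off : off + payload_len]
        if len(payload) != payload_len:
            raise FormatError("container truncated: payload shorter than declared")
    except (struct.error, IndexError) as exc:
        raise FormatError(f"container truncated: {exc}") from exc
    return ContainerInfo(
        configs=configs,
        seq_len=seq_len,
        learning_rate=float(learning_rate),
        hidden_nodes=int(hidden_nodes),
        relative=bool(flags & _FLAG_RELATIVE),
        has_reference=bool(flags & _FLAG_HAS_REFERENCE),
        include_blend=not flags & _FLAG_NO_BLEND_INPUT,
        include_derived=not flags & _FLAG_NO_DERIVED,
        ref_crc=ref_crc,
        payload=payload,
    )


def decompress(container: bytes, reference: np.ndarray | None = None) -> np.ndarray:
    """Byte-exact inverse of :func:`compress`."""
    info = read_header(container)
    if info.has_reference:
        if reference is None:
            raise ValueError("container was coded against a reference; none given")
        crc = zlib.crc32(np.asarray(reference, dtype=np.uint8).tobytes())
        if crc != info.ref_crc:
            raise ValueError("reference sequence does not match the container checksum")
    engine = CompressorEngine(
        info.configs,
        learning_rate=info.learning_rate,
        hidden_nodes=info.hidden_nodes,
        reference=reference if info.has_reference else None,
        include_blend=info.include_blend,
        include_derived=info.include_derived,
    )
    out = np.empty(info.seq_len, dtype=np.uint8)
    if info.seq_len == 0:
        return out
    dec = RangeDecoder(info.payload)
    for i in range(info.seq_len):
        probs, blend_p, x, coded = engine.predict()
        sym = dec.decode_symbol(coded)
        out[i] = sym
        engine.observe(sym, probs, blend_p, x, coded)
    return out


def emit_profile(
    seq: np.ndarray,
    target_specs=None,
    ref_specs=None,
    *,
    mode: str | None = None,
    reference: np.ndarray | None = None,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    hidden_nodes: int = DEFAULT_HIDDEN_NODES,
    disable_ir: bool = False,
    smooth_window: int = 512,
):
    """Per-symbol complexity profile: bits[n] = -log2 q(x_n) as charged by
    the coder, plus a centred moving average of width ``smooth_window``.

    Returns ``(bits, smoothed)`` float arrays of the sequence length.
    """
    if mode is not None:
        configs = preset_configs(mode)
    else:
        configs = _build_configs(target_specs, ref_specs, disable_ir)
    engine = CompressorEngine(
        configs,
        learning_rate=learning_rate,
        hidden_nodes=hidden_nodes,
        reference=reference,
    )
    seq = np.asarray(seq, dtype=np.uint8)
    bits = np.empty(len(seq))
    for i, sym in enumerate(seq):
        sym = int(sym)
        probs, blend_p, x, coded = engine.predict()
        bits[i] = quantized_bits(coded, sym)
        engine.observe(sym, probs, blend_p, x, coded)
    return bits, smooth_profile(bits, smooth_window)


def smooth_profile(bits: np.ndarray, window: int = 512) -> np.ndarray:
    """Centred moving average; partial windows at the edges use the
    available positions only."""
    if window <= 1 or len(bits) == 0:
        return np.asarray(bits, dtype=np.float64).copy()
    kernel = np.ones(min(window, len(bits)))
    num = np.convolve(bits, kernel, mode="same")
    den = np.convolve(np.ones(len(bits)), kernel, mode="same")
    return num / den


@dataclass(frozen=True)
class CostParams:
    """Inputs of the long-term storage cost model.

    processing_time in seconds, power in watts, energy_price per kWh,
    size in GB, size_price per GB.
    """

    processing_time: float = 0.0
    power: float = 0.0
    energy_price: float = 0.0
    n_copies: int = 0
    size: float = 0.0
    size_price: float = 0.0

    def __post_init__(self):
        for name in ("processing_time", "power", "energy_price", "n_copies", "size", "size_price"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def estimate_storage_cost(p: CostParams) -> float:
    """Total = processing (time x power x energy price, s->h and W->kW)
    + storage (copies x size x price per GB)."""
    processing = (p.processing_time / 3600.0) * (p.power / 1000.0) * p.energy_price
    storage = p.n_copies * p.size * p.size_price
    return processing + storage


def compressed_bits_per_base(container: bytes, seq_len: int) -> float:
    if seq_len == 0:
        return math.nan
    return 8.0 * len(container) / seq_len
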