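"""Synthetic nanopore-style libraries with context-dependent systematic errors.

Real adaptor libraries show errors that are mostly *systematic*: a 6-mer's
error rate is reproducible across replicates and rises with GC content and
homopolymer length. The generator reproduces this structure: each of the
4096 6-mers gets mismatch/insertion/deletion rates of the form

    rate = clamp(base + gc_slope * GC_fraction
                 + homopolymer_slope * (max_run - 1)
                 + offset_6mer,  0, 0.5)

where ``offset_6mer ~ Normal(0, systematic_sd)`` is frozen by the seed, so
the same model is shared by replicate libraries. Reads are an adaptor, a
sample insert and (optionally) a second adaptor; every emitted base passes
through the error channel of the 6-mer ending at it, scaled per read by the
pore (channel) multiplier. Default rates are set to the magnitude reported
for MinION data: total error near 0.09/nt, roughly one-third mismatches and
two-thirds indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (decode, encode, gc_count, index_to_kmer,
                   max_homopolymer_run, revcomp, rolling_kmer_indices)
from .errors import InvalidInputError, InvalidParameterError
from .io import FastqRead

logger = logging.getLogger(__name__)

__all__ = ["ContextErrorModel", "PoreChannel", "PoreModel", "SimConfig",
           "build_context_error_model", "default_pore_model",
           "simulate_library", "simulate_reads_from_reference",
           "simulate_mixture_pair"]

K = 6
N_KMERS = 4 ** K
_EPOCH = np.datetime64("2022-01-01T00:00:00")

# per-6-mer annotations, fixed by the k-mer string
_KMERS = [index_to_kmer(i, K) for i in range(N_KMERS)]
KMER_GC = np.array([gc_count(s) for s in _KMERS], dtype=float)
KMER_MAXRUN = np.array([max_homopolymer_run(s) for s in _KMERS], dtype=float)


@dataclass(frozen=True)
class ContextErrorModel:
    """Per-6-mer error rates (probability per emitted nucleotide)."""

    p_mismatch: np.ndarray  # (4096,)
    p_insertion: np.ndarray
    p_deletion: np.ndarray
    params: dict = field(default_factory=dict)

    def rate_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "kmer": _KMERS,
            "p_mismatch": self.p_mismatch,
            "p_insertion": self.p_insertion,
            "p_deletion": self.p_deletion,
            "p_total": self.p_mismatch + self.p_insertion + self.p_deletion,
        })


def build_context_error_model(base_mismatch: float = 0.020,
                              base_insertion: float = 0.012,
                              base_deletion: float = 0.018,
                              gc_slope: float = 0.018,
                              homopolymer_slope: float = 0.006,
                              systematic_sd: float = 0.010,
                              rng_seed: int = 0) -> ContextErrorModel:
    """Build the deterministic per-6-mer rate table (see module docstring)."""
    for name, v in [("base_mismatch", base_mismatch),
                    ("base_insertion", base_insertion),
                    ("base_deletion", base_deletion),
                    ("systematic_sd", systematic_sd)]:
        if not 0 <= v <= 0.5:
            raise InvalidParameterError(f"{name} must be in [0, 0.5], got {v}")
    rng = np.random.default_rng(rng_seed)
    rates = {}
    n_clamped = 0
    for cls, base in [("mismatch", base_mismatch),
                      ("insertion", base_insertion),
                      ("deletion", base_deletion)]:
        raw = (base + gc_slope * KMER_GC / K
               + homopolymer_slope * (KMER_MAXRUN - 1)
               + rng.normal(0.0, systematic_sd, size=N_KMERS))
        clamped = np.clip(raw, 0.0, 0.5)
        n_clamped += int((raw != clamped).sum())
        rates[cls] = clamped
    if n_clamped > 0.10 * 3 * N_KMERS:
        logger.warning("context error model clamps %d of %d rates at bounds",
                       n_clamped, 3 * N_KMERS)
    return ContextErrorModel(
        p_mismatch=rates["mismatch"], p_insertion=rates["insertion"],
        p_deletion=rates["deletion"],
        params=dict(base_mismatch=base_mismatch, base_insertion=base_insertion,
                    base_deletion=base_deletion, gc_slope=gc_slope,
                    homopolymer_slope=homopolymer_slope,
                    systematic_sd=systematic_sd, rng_seed=rng_seed))


@dataclass(frozen=True)
class PoreChannel:
    channel_id: int
    error_multiplier: float = 1.0
    throughput_weight: float = 1.0
    active_until: float = float("inf")  # seconds from run start


@dataclass(frozen=True)
class PoreModel:
    channels: tuple[PoreChannel, ...]

    def __post_init__(self):
        if not self.channels:
            raise InvalidParameterError("pore model needs at least one channel")
        if any(c.error_multiplier <= 0 or c.throughput_weight <= 0
               for c in self.channels):
            raise InvalidParameterError(
                "error multipliers and throughput weights must be > 0")


def default_pore_model(n_channels: int = 16, multiplier_sd: float = 0.3,
                       rng_seed: int = 0,
                       run_duration: float = float("inf")) -> PoreModel:
    """Channels with log-normally spread error multipliers around 1."""
    rng = np.random.default_rng(rng_seed)
    mult = np.exp(rng.normal(0.0, multiplier_sd, size=n_channels))
    return PoreModel(tuple(
        PoreChannel(channel_id=i + 1, error_multiplier=float(m),
                    throughput_weight=1.0, active_until=run_duration)
        for i, m in enumerate(mult)))


@dataclass(frozen=True)
class SimConfig:
    n_reads: int = 1000
    insert_length_mean: float = 150.0
    insert_length_sd: float = 30.0
    attach_3prime: bool = True
    run_duration: float = 8 * 3600.0  # seconds
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_reads < 1:
            raise InvalidParameterError("n_reads must be >= 1")
        if self.insert_length_mean < 0 or self.insert_length_sd < 0:
            raise InvalidParameterError("insert lengths must be >= 0")


def apply_error_channel(codes: np.ndarray, model: ContextErrorModel,
                        multiplier: float, rng: np.random.Generator):
    """Pass one encoded template through the error channel.

    At most one event per template position: deletion (base skipped),
    insertion (base emitted, then one uniform random extra base), or
    mismatch (base replaced by one of the other three). Returns
    (emitted codes, n_sub, n_ins, n_del).
    """
    n = len(codes)
    kidx = rolling_kmer_indices(codes, K)
    p_del = np.minimum(model.p_deletion[kidx] * multiplier, 0.5)
    p_ins = np.minimum(model.p_insertion[kidx] * multiplier, 0.5)
    p_mis = np.minimum(model.p_mismatch[kidx] * multiplier, 0.5)
    u = rng.random(n)
    del_mask = u < p_del
    ins_mask = ~del_mask & (u < p_del + p_ins)
    mis_mask = ~del_mask & ~ins_mask & (u < p_del + p_ins + p_mis)
    emitted = codes.copy()
    n_mis = int(mis_mask.sum())
    if n_mis:
        emitted[mis_mask] = (emitted[mis_mask]
                             + rng.integers(1, 4, size=n_mis)) % 4
    counts = (~del_mask).astype(np.int64) + ins_mask
    out = np.repeat(emitted, counts)
    n_ins = int(ins_mask.sum())
    if n_ins:
        second_copy = np.cumsum(counts)[ins_mask] - 1
        out[second_copy] = rng.integers(0, 4, size=n_ins)
    return out, n_mis, n_ins, int(del_mask.sum())


def _iso(seconds: float) -> str:
    t = _EPOCH + np.timedelta64(int(round(seconds)), "s")
    return str(t) + "Z"


def _pick_channel(pore_model: PoreModel, t: float,
                  rng: np.random.Generator) -> PoreChannel:
    active = [c for c in pore_model.channels if c.active_until > t]
    if not active:
        active = list(pore_model.channels)  # run past last pore: reuse all
    w = np.array([c.throughput_weight for c in active])
    return active[rng.choice(len(active), p=w / w.sum())]


def simulate_library(panel, manifest, sample_refs: dict[str, str],
                     error_model: ContextErrorModel,
                     pore_model: PoreModel | None = None,
                     sim_config: SimConfig = SimConfig(),
                     read_prefix: str = "read",
                     abundance: dict[str, float] | None = None,
                     adaptor_weights: np.ndarray | None = None,
                     ) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate one library of adaptor-flanked reads.

    Each read is a manifest-weighted adaptor, an insert drawn from
    ``sample_refs`` (feature weighted by ``abundance`` if given) and,
    optionally, an independently drawn 3' adaptor. Half the reads are
    emitted reverse-complemented. Returns the reads and a ground-truth
    table (read_id, captor_id, channel, start_time, insert_ref,
    orientation, n_sub, n_ins, n_del).
    """
    if not sample_refs:
        raise InvalidInputError("sample_refs is empty")
    by_id = {a.id: a for a in panel}
    missing = [e.captor_id for e in manifest.entries if e.captor_id not in by_id]
    if missing:
        raise InvalidInputError(
            f"manifest ids not in panel: {missing[:3]}...")
    rng = np.random.default_rng(sim_config.rng_seed)
    if pore_model is None:
        pore_model = default_pore_model(rng_seed=sim_config.rng_seed,
                                        run_duration=sim_config.run_duration)
    ids = manifest.ids
    probs = manifest.fractions
    if adaptor_weights is not None:
        probs = probs * np.asarray(adaptor_weights, dtype=float)
        probs = probs / probs.sum()
    adaptor_codes = {a.id: encode(a.full_sequence) for a in panel}
    feat_names = list(sample_refs)
    feat_codes = [encode(sample_refs[f]) for f in feat_names]
    if abundance is None:
        feat_probs = np.full(len(feat_names), 1.0 / len(feat_names))
    else:
        feat_probs = np.array([abundance[f] for f in feat_names], dtype=float)
        feat_probs = feat_probs / feat_probs.sum()

    n = sim_config.n_reads
    adaptor_draw = rng.choice(len(ids), size=n, p=probs)
    feat_draw = rng.choice(len(feat_names), size=n, p=feat_probs)
    lengths = np.maximum(
        np.round(rng.normal(sim_config.insert_length_mean,
                            sim_config.insert_length_sd, size=n)), 0
    ).astype(np.int64)
    times = np.sort(rng.uniform(0.0, sim_config.run_duration, size=n))
    rev = rng.random(n) < 0.5

    reads: list[FastqRead] = []
    truth_rows = []
    for r in range(n):
        cid = ids[adaptor_draw[r]]
        fname = feat_names[feat_draw[r]]
        fcodes = feat_codes[feat_draw[r]]
        ins_len = min(int(lengths[r]), len(fcodes))
        start = int(rng.integers(0, len(fcodes) - ins_len + 1))
        parts = [adaptor_codes[cid], fcodes[start:start + ins_len]]
        if sim_config.attach_3prime:
            cid3 = ids[int(rng.choice(len(ids), p=probs))]
            parts.append(adaptor_codes[cid3])
        template = np.concatenate(parts)
        channel = _pick_channel(pore_model, times[r], rng)
        out, n_sub, n_ins, n_del = apply_error_channel(
            template, error_model, channel.error_multiplier, rng)
        seq = decode(out)
        orientation = "+"
        if rev[r]:
            seq = revcomp(seq)
            orientation = "-"
        rid = f"{read_prefix}_{r:06d}"
        start_time = _iso(times[r])
        reads.append(FastqRead(
            header=f"{rid} ch={channel.channel_id} start_time={start_time}",
            sequence=seq, quality="I" * len(seq)))
        truth_rows.append((rid, cid, channel.channel_id, start_time, fname,
                           orientation, n_sub, n_ins, n_del))
    truth = pd.DataFrame(truth_rows, columns=[
        "read_id", "captor_id", "channel", "start_time", "insert_ref",
        "orientation", "n_sub", "n_ins", "n_del"])
    return reads, truth


def simulate_reads_from_reference(reference: str, n_reads: int,
                                  error_model: ContextErrorModel,
                                  rng_seed: int = 0,
                                  variant_positions: dict[int, float]
                                  | None = None,
                                  multiplier: float = 1.0
                                  ) -> list[np.ndarray]:
    """Full-length encoded reads of one reference through the error channel.

    ``variant_positions`` maps 0-based positions to variant allele fractions:
    before the error channel, each read substitutes a fixed alternative base
    at that position with the given probability (emulating true variants in
    sample DNA, absent from the matched control).
    """
    rng = np.random.default_rng(rng_seed)
    base = encode(reference)
    alt = {p: (int(base[p]) + 1 + int(rng.integers(0, 3))) % 4
           for p in (variant_positions or {})}
    reads = []
    for _ in range(n_reads):
        template = base.copy()
        for pos, vaf in (variant_positions or {}).items():
            if rng.random() < vaf:
                template[pos] = alt[pos]
        out, *_ = apply_error_channel(template, error_model, multiplier, rng)
        reads.append(out)
    return reads


def simulate_mixture_pair(panel, manifest, sample_refs: dict[str, str],
                          fold_change_spec: dict[str, float],
                          replicates: int,
                          error_model: ContextErrorModel,
                          sim_config: SimConfig = SimConfig(),
                          rng_seed: int = 0,
                          batch_sd: float = 0.0,
                          size_sd: float = 0.25):
    """Two conditions x ``replicates`` libraries with known fold changes.

    Condition B's feature abundances are condition A's times
    2^fold_change_spec. All libraries share the adaptor master mix. Each
    library gets a library-size scalar 2^N(0, size_sd) and a batch scalar
    b ~ N(0, batch_sd); the batch scalar perturbs the draw probabilities of
    every feature *and* adaptor through fixed per-sequence loadings
    (prob scaled by 2^(b * loading)), emulating shared unwanted variation
    that control-anchored normalisation can estimate and remove. Returns
    (libraries, meta) where libraries is {"A": [...], "B": [...]} of
    (reads, truth) pairs and meta records the per-library scalars.
    """
    if replicates < 1:
        raise InvalidParameterError("replicate count must be >= 1")
    unknown = [f for f in fold_change_spec if f not in sample_refs]
    if unknown:
        raise InvalidInputError(f"fold-change features not in refs: {unknown}")
    rng = np.random.default_rng(rng_seed)
    feat_names = list(sample_refs)
    feat_loading = {f: float(rng.normal()) for f in feat_names}
    adaptor_loading = rng.normal(size=len(manifest.ids))
    base_abund = {f: 1.0 for f in feat_names}
    abund = {
        "A": base_abund,
        "B": {f: base_abund[f] * 2.0 ** fold_change_spec.get(f, 0.0)
              for f in feat_names},
    }
    libraries = {"A": [], "B": []}
    meta_rows = []
    base_total = sum(base_abund.values())
    for cond in ("A", "B"):
        # depth compensation: expected per-feature counts follow 2^spec
        # exactly (a doubled feature yields doubled counts, not a
        # renormalised share), emulating more input material
        depth_factor = sum(abund[cond].values()) / base_total
        for rep in range(replicates):
            sub = int(rng.integers(0, 2 ** 31))
            b = float(rng.normal(0.0, batch_sd)) if batch_sd > 0 else 0.0
            size = float(2.0 ** rng.normal(0.0, size_sd)) if size_sd > 0 else 1.0
            n_reads = max(1, int(round(sim_config.n_reads * size
                                       * depth_factor)))
            cfg = SimConfig(
                n_reads=n_reads,
                insert_length_mean=sim_config.insert_length_mean,
                insert_length_sd=sim_config.insert_length_sd,
                attach_3prime=sim_config.attach_3prime,
                run_duration=sim_config.run_duration,
                rng_seed=sub)
            ab = {f: abund[cond][f] * 2.0 ** (b * feat_loading[f])
                  for f in feat_names}
            aw = 2.0 ** (b * adaptor_loading)
            reads, truth = simulate_library(
                panel, manifest, sample_refs, error_model,
                sim_config=cfg, read_prefix=f"{cond}{rep}",
                abundance=ab, adaptor_weights=aw)
            libraries[cond].append((reads, truth))
            meta_rows.append((cond, rep, n_reads, b, size, sub))
    meta = pd.DataFrame(meta_rows, columns=[
        "condition", "replicate", "n_reads", "batch_scalar", "size_scalar",
        "rng_seed"])
    meta.attrs["fold_change_spec"] = dict(fold_change_spec)
    meta.attrs["feature_loading"] = feat_loading
    return libraries, meta
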