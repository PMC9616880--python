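"""Per-nucleotide and per-6-mer error profiles, pore/time summaries and
control-anchored per-nucleotide error subtraction.

Rates are events/depth at positions with depth >= ``min_depth`` (absent
elsewhere, represented as NaN). The 6-mer table averages each adaptor's
per-position rates over the 25 overlapping 6-mer windows of its 30-nt
variable region, then averages across all (adaptor, window) instances of
the same 6-mer. Error subtraction removes a matched control's systematic
per-position error from a sample profile, clamped at zero — the mechanism
by which a gene-specific control adaptor sharpens variant signal in the
accompanying patient DNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import gc_count, max_homopolymer_run
from .align import EventProfile, ReadClassification
from .errors import ConsistencyError, InvalidInputError, InvalidParameterError
from .io import BedInterval

logger = logging.getLogger(__name__)

CLASSES = ("mismatch", "insertion", "deletion", "total")

__all__ = ["PositionErrorProfile", "CorrectionReport", "profile_rates",
           "kmer_table", "compare_tables", "pore_time_summary",
           "subtract_profiles", "restrict_to_variants", "profile_correlation",
           "CLASSES"]


@dataclass
class PositionErrorProfile:
    """Per-position error rates for one reference; NaN where depth < min."""

    reference_id: str
    reference_seq: str
    r_mismatch: np.ndarray
    r_insertion: np.ndarray
    r_deletion: np.ndarray
    depth: np.ndarray
    min_depth: int = 10

    @property
    def r_total(self) -> np.ndarray:
        return self.r_mismatch + self.r_insertion + self.r_deletion

    def rate(self, cls: str) -> np.ndarray:
        if cls == "total":
            return self.r_total
        return getattr(self, f"r_{cls}")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.r_mismatch)

    def __len__(self) -> int:
        return len(self.depth)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(len(self)),
            "ref_base": list(self.reference_seq),
            "r_mismatch": self.r_mismatch, "r_insertion": self.r_insertion,
            "r_deletion": self.r_deletion, "r_total": self.r_total,
            "depth": self.depth})


def profile_rates(events: EventProfile, min_depth: int = 10
                  ) -> PositionErrorProfile:
    """Counts/depth per position; positions below ``min_depth`` are NaN."""
    if min_depth < 1:
        raise InvalidParameterError("min_depth must be >= 1")
    depth = events.depth.astype(float)
    ok = depth >= min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        rm = np.where(ok, events.n_mismatch / depth, np.nan)
        ri = np.where(ok, events.n_insertion / depth, np.nan)
        rd = np.where(ok, events.n_deletion / depth, np.nan)
    return PositionErrorProfile(
        reference_id=events.reference_id, reference_seq=events.reference_seq,
        r_mismatch=rm, r_insertion=ri, r_deletion=rd,
        depth=events.depth.copy(), min_depth=min_depth)


def kmer_table(profiles: dict[str, PositionErrorProfile], panel,
               k: int = 6) -> pd.DataFrame:
    """Mean per-6-mer rates over all (adaptor, window) instances.

    Each adaptor's variable region contributes one instance per overlapping
    k-mer window; a window's rate (per class) is the unweighted mean over
    its k positions. Windows containing any undefined position are skipped.
    Columns: kmer, mean_r_{mismatch,insertion,deletion,total}, n_instances,
    gc_count, max_homopolymer_run.
    """
    missing = [a.id for a in panel if a.id not in profiles]
    if missing:
        raise ConsistencyError(f"profiles missing for adaptors {missing[:3]}")
    acc: dict[str, list[np.ndarray]] = {}
    n_skipped = 0
    for a in panel:
        prof = profiles[a.id]
        off = len(a.constant5)
        var = a.variable
        rates = np.stack([prof.r_mismatch, prof.r_insertion, prof.r_deletion])
        for w in range(len(var) - k + 1):
            window = rates[:, off + w:off + w + k]
            if np.isnan(window).any():
                n_skipped += 1
                continue
            acc.setdefault(var[w:w + k], []).append(window.mean(axis=1))
    if n_skipped:
        logger.info("kmer_table: skipped %d windows with undefined positions",
                    n_skipped)
    rows = []
    for kmer in sorted(acc):
        inst = np.stack(acc[kmer])
        means = inst.mean(axis=0)
        rows.append({
            "kmer": kmer,
            "mean_r_mismatch": means[0], "mean_r_insertion": means[1],
            "mean_r_deletion": means[2], "mean_r_total": means.sum(),
            "n_instances": len(inst),
            "gc_count": gc_count(kmer),
            "max_homopolymer_run": max_homopolymer_run(kmer)})
    return pd.DataFrame(rows)


def compare_tables(table_a: pd.DataFrame, table_b: pd.DataFrame
                   ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-6-mer |a - b| and the symmetric mean relative difference (%).

    The summary per error class is mean over shared 6-mers of
    100*|a - b| / ((a + b)/2), excluding 6-mers where both rates are zero.
    """
    merged = table_a.merge(table_b, on="kmer", suffixes=("_a", "_b"))
    if merged.empty:
        raise InvalidInputError("tables share no 6-mers")
    diffs = {"kmer": merged.kmer}
    summary = {}
    for cls in CLASSES:
        a = merged[f"mean_r_{cls}_a"].to_numpy(float)
        b = merged[f"mean_r_{cls}_b"].to_numpy(float)
        diffs[f"delta_{cls}"] = np.abs(a - b)
        mean_ab = (a + b) / 2
        ok = mean_ab > 0
        rel = 100.0 * np.abs(a - b)[ok] / mean_ab[ok]
        summary[cls] = float(rel.mean()) if ok.any() else float("nan")
    return pd.DataFrame(diffs), summary


def pore_time_summary(per_read: pd.DataFrame, time_bin: float = 3600.0,
                      run_duration: float | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean per-read error by channel and time bin.

    ``per_read`` needs columns read_id, channel, start_time (ISO-8601 or
    seconds), per_read_error. Returns (per channel x bin table, per channel
    summary with overall mean, throughput and max/min bin ratio).
    """
    df = per_read.dropna(subset=["channel"]).copy()
    if df.empty:
        logger.warning("no reads carry channel metadata")
        empty = pd.DataFrame(columns=["channel", "time_bin", "n_reads",
                                      "mean_error"])
        return empty, pd.DataFrame(columns=["channel", "n_reads",
                                            "mean_error", "bin_ratio"])
    t = df["start_time"]
    if t.dtype == object:
        parsed = pd.to_datetime(t.str.replace("Z", ""), errors="coerce")
        seconds = (parsed - parsed.min()).dt.total_seconds()
    else:
        seconds = t.astype(float)
    df["seconds"] = seconds
    if run_duration is None:
        run_duration = float(df.seconds.max()) + 1e-9
    n_bins = max(1, int(np.ceil(run_duration / time_bin)))
    late = df.seconds >= n_bins * time_bin
    if late.any():
        logger.info("%d reads past run duration clamped to final bin",
                    int(late.sum()))
    df["time_bin"] = np.minimum(
        (df.seconds // time_bin).astype(int), n_bins - 1)
    binned = (df.groupby(["channel", "time_bin"])
              .agg(n_reads=("read_id", "size"),
                   mean_error=("per_read_error", "mean"))
              .reset_index())
    per_channel = []
    for ch, grp in binned.groupby("channel"):
        ratio = (grp.mean_error.max() / grp.mean_error.min()
                 if (grp.mean_error > 0).all() else np.nan)
        sub = df[df.channel == ch]
        per_channel.append({
            "channel": ch, "n_reads": int(sub.shape[0]),
            "mean_error": float(sub.per_read_error.mean()),
            "bin_ratio": float(ratio)})
    return binned, pd.DataFrame(per_channel)


@dataclass
class CorrectionReport:
    """Outcome of per-nucleotide control subtraction."""

    positions: np.ndarray
    sample_rates: dict[str, np.ndarray]   # per class incl. total
    control_rates: dict[str, np.ndarray]
    corrected_rates: dict[str, np.ndarray]
    mask: np.ndarray | None = None  # restriction mask (variant positions)

    def _sel(self) -> np.ndarray:
        ok = ~(np.isnan(self.sample_rates["total"])
               | np.isnan(self.control_rates["total"]))
        if self.mask is not None:
            ok &= self.mask
        return ok

    def summary(self) -> dict[str, dict[str, float]]:
        """Median rate before/after correction per error class."""
        ok = self._sel()
        if not ok.any():
            logger.warning("correction summary over an empty position set")
            return {cls: {"median_before": float("nan"),
                          "median_after": float("nan")} for cls in CLASSES}
        return {cls: {
            "median_before": float(np.median(self.sample_rates[cls][ok])),
            "median_after": float(np.median(self.corrected_rates[cls][ok])),
        } for cls in CLASSES}


def _rates_dict(p: PositionErrorProfile) -> dict[str, np.ndarray]:
    return {"mismatch": p.r_mismatch, "insertion": p.r_insertion,
            "deletion": p.r_deletion, "total": p.r_total}


def subtract_profiles(sample: PositionErrorProfile,
                      control: PositionErrorProfile) -> CorrectionReport:
    """corrected = max(0, sample - control) per position and error class.

    Sample and control must describe the same reference frame (equal
    length, 1:1 positions).
    """
    if len(sample) != len(control):
        raise ConsistencyError(
            f"profile lengths differ: sample {len(sample)} vs control "
            f"{len(control)} (not the same reference frame)")
    s, c = _rates_dict(sample), _rates_dict(control)
    corrected = {cls: np.maximum(s[cls] - c[cls], 0.0) for cls in CLASSES}
    return CorrectionReport(
        positions=np.arange(len(sample)), sample_rates=s, control_rates=c,
        corrected_rates=corrected)


def restrict_to_variants(report: CorrectionReport,
                         positions: list[BedInterval] | np.ndarray
                         ) -> CorrectionReport:
    """Recompute summaries over a masked set of positions only."""
    n = len(report.positions)
    mask = np.zeros(n, dtype=bool)
    if isinstance(positions, np.ndarray):
        if positions.size and (positions.min() < 0 or positions.max() >= n):
            raise InvalidParameterError("variant positions outside profile")
        mask[positions] = True
    else:
        for iv in positions:
            if iv.start < 0 or iv.end > n:
                raise InvalidParameterError(
                    f"interval {iv.name} outside profile coordinates")
            mask[iv.start:iv.end] = True
    if not mask.any():
        logger.warning("variant restriction mask is empty")
    return CorrectionReport(
        positions=report.positions, sample_rates=report.sample_rates,
        control_rates=report.control_rates,
        corrected_rates=report.corrected_rates, mask=mask)


def profile_correlation(sample: PositionErrorProfile,
                        control: PositionErrorProfile
                        ) -> dict[str, float]:
    """Pearson correlation of per-position rates, per error class."""
    if len(sample) != len(control):
        raise ConsistencyError("profiles have different lengths")
    s, c = _rates_dict(sample), _rates_dict(control)
    out = {}
    for cls in CLASSES:
        ok = ~(np.isnan(s[cls]) | np.isnan(c[cls]))
        if ok.sum() < 3:
            raise InvalidInputError(
                f"fewer than 3 shared defined positions for {cls}")
        x, y = s[cls][ok], c[cls][ok]
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("zero variance in %s rates; correlation undefined",
                           cls)
            out[cls] = float("nan")
            continue
        out[cls] = float(stats.pearsonr(x, y).statistic)
    return out
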