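"""Quantitative ladders, limit of quantification, depth analyses, feature
counting and between-sample normalisation (TMM, control-anchored RUVg).

The staggered master mix turns observed adaptor counts into an internal
reference ladder: ordinary least squares of log2 observed count on log2
relative concentration measures a library's quantitative accuracy (slope,
R^2). At low input the relation breaks down; a continuous two-segment
piecewise-linear fit locates the inflection, whose observed-count
coordinate is reported as the limit of quantification (LOQ) in reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import UNASSIGNED, UNCLASSIFIED, ReadClassification
from .errors import (InsufficientDataError, InvalidInputError,
                     InvalidParameterError)

logger = logging.getLogger(__name__)

__all__ = ["LadderFit", "SegmentalFit", "CountMatrix", "captor_counts",
           "ladder_fit", "segmental_fit", "subsample_reads",
           "min_reliable_depth", "feature_counts", "build_count_matrix",
           "tmm_factors", "ruvg_normalize", "fold_change_eval", "loq_flag"]


@dataclass(frozen=True)
class LadderFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_ci_halfwidth: float
    not_detected: tuple[str, ...] = ()


@dataclass(frozen=True)
class SegmentalFit:
    breakpoint_x: float          # log2 expected-concentration coordinate
    breakpoint_log2_reads: float  # fitted log2 observed count at the kink
    left_slope: float
    right_slope: float
    left_r2: float
    right_r2: float
    sse: float
    degenerate: bool = False

    @property
    def breakpoint_reads(self) -> float:
        """The LOQ on the count scale (reads)."""
        return float(2.0 ** self.breakpoint_log2_reads)


@dataclass
class CountMatrix:
    """Non-negative feature x sample counts with control-row flags."""

    counts: pd.DataFrame            # index: features, columns: samples
    is_control: pd.Series           # bool, indexed like counts

    def __post_init__(self):
        if (self.counts.to_numpy(float) < 0).any():
            raise InvalidInputError("count matrix has negative entries")
        self.is_control = self.is_control.reindex(self.counts.index,
                                                  fill_value=False)

    @property
    def control_ids(self) -> list[str]:
        return list(self.is_control.index[self.is_control])

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.insert(0, "is_control", self.is_control)
        df.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        df.index.name = None
        is_control = df.pop("is_control").astype(bool)
        return cls(counts=df, is_control=is_control)


def captor_counts(classifications) -> tuple[pd.Series, int]:
    """Reads per adaptor from 5'-classified reads.

    Accepts ReadClassification objects or a DataFrame with a captor_id
    column. Returns (counts, n_unclassified).
    """
    if isinstance(classifications, pd.DataFrame):
        ids = classifications["captor_id"]
    else:
        ids = pd.Series([c.captor_id for c in classifications], dtype=object)
    n_uncl = int((ids == UNCLASSIFIED).sum())
    counts = ids[ids != UNCLASSIFIED].value_counts().sort_index()
    if counts.empty:
        logger.warning("no classified reads; counts are empty")
    return counts, n_uncl


def ladder_fit(counts: pd.Series, manifest) -> LadderFit:
    """OLS of log2 observed count on log2 relative concentration.

    Zero-count adaptors are excluded from the fit and reported as not
    detected. The slope CI half-width is t_{0.975, n-2} * SE(slope).
    """
    x, y, missing = [], [], []
    for e in manifest.entries:
        c = int(counts.get(e.captor_id, 0))
        if c > 0:
            x.append(np.log2(e.relative_concentration))
            y.append(np.log2(c))
        else:
            missing.append(e.captor_id)
    if len(x) < 3:
        raise InsufficientDataError(
            f"only {len(x)} adaptors with positive counts; need >= 3")
    res = stats.linregress(x, y)
    n = len(x)
    ci = float(stats.t.ppf(0.975, n - 2) * res.stderr) if n > 2 else np.inf
    return LadderFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2), n_points=n,
                     slope_ci_halfwidth=ci, not_detected=tuple(missing))


def segmental_fit(points: np.ndarray | list[tuple[float, float]],
                  slope_tol: float = 1e-8) -> SegmentalFit:
    """Continuous two-segment piecewise-linear least squares.

    ``points`` are (log2 expected concentration, log2 observed count). The
    breakpoint is grid-searched over midpoints between consecutive distinct
    sorted x values, minimising total SSE of the model
    y = b0 + b1 x + b2 (x - c)_+ . Left/right slopes are b1 and b1 + b2;
    per-segment R^2 is computed from the fitted model on each side. When
    the best fit has |b2| < slope_tol the data are effectively collinear
    and the fit is flagged degenerate (breakpoint at the grid boundary).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points must be (n, 2)")
    if len(pts) < 6:
        raise InsufficientDataError(
            f"segmental regression needs >= 6 points, got {len(pts)}")
    order = np.argsort(pts[:, 0], kind="stable")
    x, y = pts[order, 0], pts[order, 1]
    ux = np.unique(x)
    if len(ux) < 3:
        raise InsufficientDataError("need >= 3 distinct x values")
    # midpoints between consecutive distinct sorted x values
    candidates = (ux[:-1] + ux[1:]) / 2.0
    best = None
    for c in candidates:
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(c), beta)
    sse, c, beta = best
    b0, b1, b2 = (float(v) for v in beta)
    degenerate = abs(b2) < slope_tol
    if degenerate:
        c = float(candidates[0])

    def seg_r2(mask: np.ndarray) -> float:
        if mask.sum() < 2 or np.var(y[mask]) == 0:
            return float("nan")
        X = np.column_stack([np.ones(mask.sum()), x[mask],
                             np.maximum(x[mask] - c, 0.0)])
        resid = y[mask] - X @ beta
        return float(1.0 - (resid @ resid) / (mask.sum() * np.var(y[mask])))

    left, right = x < c, x >= c
    y_at_c = b0 + b1 * c
    return SegmentalFit(
        breakpoint_x=c, breakpoint_log2_reads=float(y_at_c),
        left_slope=b1, right_slope=b1 + b2,
        left_r2=seg_r2(left), right_r2=seg_r2(right),
        sse=sse, degenerate=degenerate)


def subsample_reads(reads: list, n: int | None = None,
                    fraction: float | None = None,
                    rng_seed: int = 0) -> list:
    """Uniform sample of reads without replacement, order-preserving."""
    if (n is None) == (fraction is None):
        raise InvalidParameterError("give exactly one of n or fraction")
    if fraction is not None:
        if not 0 <= fraction <= 1:
            raise InvalidParameterError("fraction must be in [0, 1]")
        n = int(round(fraction * len(reads)))
    if n > len(reads) or n < 0:
        raise InvalidParameterError(
            f"cannot sample {n} of {len(reads)} reads")
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


def min_reliable_depth(classifications: list, manifest, depths: list[int],
                       min_count: int = 5, min_r2: float = 0.95,
                       rng_seed: int = 0
                       ) -> tuple[int | None, pd.DataFrame]:
    """Smallest depth at which quantification is reliable.

    Reads (already classified; classification is per-read deterministic, so
    subsampling classifications equals classifying subsampled reads) are
    subsampled to each depth; the default criterion requires every manifest
    adaptor detected with count >= ``min_count`` and ladder R^2 >= ``min_r2``.
    Returns (depth or None, per-depth diagnostics).
    """
    if sorted(depths) != list(depths):
        raise InvalidParameterError("depths must be sorted ascending")
    rows = []
    answer = None
    for d in depths:
        if d > len(classifications):
            raise InvalidParameterError(
                f"depth {d} exceeds library size {len(classifications)}")
        sub = subsample_reads(classifications, n=d, rng_seed=rng_seed)
        counts, _ = captor_counts(sub)
        n_detected = sum(int(counts.get(e.captor_id, 0)) >= min_count
                         for e in manifest.entries)
        all_detected = n_detected == len(manifest.entries)
        try:
            fit = ladder_fit(counts, manifest)
            r2 = fit.r_squared
        except InsufficientDataError:
            r2 = float("nan")
        ok = all_detected and not np.isnan(r2) and r2 >= min_r2
        rows.append({"depth": d, "n_detected": n_detected,
                     "r_squared": r2, "reliable": ok})
        if ok and answer is None:
            answer = d
    return answer, pd.DataFrame(rows)


def feature_counts(assignments: list[tuple[str, tuple[int, int] | None]],
                   feature_lengths: dict[str, int]) -> pd.Series:
    """Mean aligned read depth per feature.

    Each assignment is (feature_id, (start, end) on the feature);
    count(feature) = sum of aligned insert bases / feature length.
    """
    aligned = {f: 0.0 for f in feature_lengths}
    for fid, span in assignments:
        if fid == UNASSIGNED or span is None:
            continue
        if fid not in aligned:
            raise InvalidInputError(f"assignment to unknown feature {fid!r}")
        aligned[fid] += span[1] - span[0]
    return pd.Series({f: aligned[f] / feature_lengths[f]
                      for f in feature_lengths})


def build_count_matrix(columns: dict[str, tuple[pd.Series, pd.Series]]
                       ) -> CountMatrix:
    """Assemble a CountMatrix from per-sample (feature_counts, captor_counts).

    Adaptor rows are appended below feature rows and flagged is_control.
    """
    feat = pd.DataFrame({s: fc for s, (fc, _) in columns.items()})
    ctrl = pd.DataFrame({s: cc for s, (_, cc) in columns.items()})
    counts = pd.concat([feat, ctrl]).fillna(0.0)
    is_control = pd.Series(
        [False] * len(feat) + [True] * len(ctrl),
        index=list(feat.index) + list(ctrl.index))
    return CountMatrix(counts=counts, is_control=is_control)


def _as_counts(matrix) -> pd.DataFrame:
    return matrix.counts if isinstance(matrix, CountMatrix) else matrix


def tmm_factors(matrix, trim_m: float = 0.3, trim_a: float = 0.05,
                ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Per sample against the reference: M and A values on library-size-scaled
    counts over features positive in both, double-trimmed (``trim_m`` from
    each M tail, ``trim_a`` from each A tail), then a precision-weighted
    mean of M gives the log2 factor. The reference is the sample whose
    upper quartile of scaled counts is closest to the mean upper quartile.
    """
    counts = _as_counts(matrix)
    if counts.shape[1] < 2:
        raise InvalidParameterError("TMM needs >= 2 samples")
    lib = counts.sum(axis=0)
    zero_lib = lib[lib == 0]
    if len(zero_lib):
        raise InvalidInputError(
            f"sample {zero_lib.index[0]!r} has all-zero counts")
    if ref_sample is None:
        uq = counts[counts > 0].div(lib, axis=1).quantile(0.75)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    log_factors = {}
    yr = counts[ref_sample].to_numpy(float)
    nr = float(lib[ref_sample])
    for s in counts.columns:
        if s == ref_sample:
            log_factors[s] = 0.0
            continue
        ys = counts[s].to_numpy(float)
        ns = float(lib[s])
        ok = (ys > 0) & (yr > 0)
        if ok.sum() < 1:
            raise InvalidInputError(
                f"samples {s!r} and {ref_sample!r} share no positive features")
        m = np.log2((ys[ok] / ns) / (yr[ok] / nr))
        a = 0.5 * np.log2((ys[ok] / ns) * (yr[ok] / nr))
        # precision weights: inverse asymptotic variance of M
        v = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        w = 1.0 / v
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        rm = stats.rankdata(m, method="ordinal")
        ra = stats.rankdata(a, method="ordinal")
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        denom = w[keep].sum()
        log_factors[s] = (float((w[keep] * m[keep]).sum() / denom)
                          if denom > 0 else 0.0)
    f = pd.Series(log_factors).reindex(counts.columns)
    f = f - f.mean()  # geometric mean of 2^f equals 1
    return 2.0 ** f


def ruvg_normalize(matrix, control_ids: list[str] | None = None,
                   k: int = 1) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove unwanted variation estimated from negative-control rows.

    log(count + 1) on control rows is row-centred; the first ``k`` left
    singular directions over samples form W; W is regressed out of every
    (log-scale) row. Returns (corrected matrix on the count scale, W).
    """
    counts = _as_counts(matrix)
    if control_ids is None:
        if not isinstance(matrix, CountMatrix):
            raise InvalidParameterError("control_ids required")
        control_ids = matrix.control_ids
    missing = [c for c in control_ids if c not in counts.index]
    if missing:
        raise InvalidParameterError(f"controls not in matrix: {missing[:3]}")
    n_samples = counts.shape[1]
    if not 1 <= k < n_samples:
        raise InvalidParameterError(
            f"k must be in [1, n_samples - 1] = [1, {n_samples - 1}]")
    if k == n_samples - 1 and n_samples > 2:
        logger.warning("k = n_samples - 1: likely over-correction")
    logy = np.log(counts.to_numpy(float) + 1.0)
    ctrl_idx = counts.index.get_indexer(control_ids)
    z = logy[ctrl_idx]                      # controls x samples
    z = z - z.mean(axis=1, keepdims=True)   # row-centred
    # SVD over samples: z.T = U S Vt, W = first k sample-space directions
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    w = u[:, :k] * s[:k]                    # samples x k
    design = np.column_stack([np.ones(n_samples), w])
    # regress each row's log counts on [1, W]; remove only the W component
    coef, *_ = np.linalg.lstsq(design, logy.T, rcond=None)
    corrected_log = logy - (w @ coef[1:, :]).T
    corrected = np.maximum(np.exp(corrected_log) - 1.0, 0.0)
    return pd.DataFrame(corrected, index=counts.index,
                        columns=counts.columns), w


def fold_change_eval(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                     expected_log2fc: dict[str, float],
                     detect_threshold: float = 1.0,
                     pseudocount: float = 0.5,
                     normalize: str = "none") -> dict:
    """Observed vs expected log2 fold changes between two conditions.

    Columns are replicates; the observed log2FC per feature is
    log2(mean_B / mean_A) with a pseudocount. ``normalize="proportion"``
    scales each column to within-sample proportions first (cancels library
    size but introduces compositional closure — a doubled feature depresses
    the others' shares); ``"none"`` takes the values as given, for matrices
    that are already size-normalised or batch-corrected. Detection means
    |observed| >= ``detect_threshold``; TPR is evaluated over features with
    |expected| >= threshold, TNR over features with expected = 0.
    """
    if matrix_a.shape[1] < 2 or matrix_b.shape[1] < 2:
        raise InvalidParameterError("need >= 2 replicates per condition")
    if normalize not in ("none", "proportion"):
        raise InvalidParameterError(f"unknown normalize mode {normalize!r}")
    features = [f for f in expected_log2fc if f in matrix_a.index]
    if not features:
        raise InvalidInputError("no expected features present in matrices")

    def cond_mean(m: pd.DataFrame) -> pd.Series:
        p = m + pseudocount
        if normalize == "proportion":
            p = p.div(p.sum(axis=0), axis=1)
        return p.loc[features].mean(axis=1)

    ma, mb = cond_mean(matrix_a), cond_mean(matrix_b)
    observed = np.log2(mb / ma)
    expected = pd.Series({f: expected_log2fc[f] for f in features})
    table = pd.DataFrame({"expected_log2fc": expected,
                          "observed_log2fc": observed})
    table["detected"] = table.observed_log2fc.abs() >= detect_threshold
    if expected.nunique() > 1:
        res = stats.linregress(expected, observed)
        slope, r2 = float(res.slope), float(res.rvalue ** 2)
    else:
        slope, r2 = float("nan"), float("nan")
    pos = expected.abs() >= detect_threshold
    neg = expected == 0
    tpr = float(table.detected[pos].mean()) if pos.any() else float("nan")
    tnr = float((~table.detected[neg]).mean()) if neg.any() else float("nan")
    rmse = float(np.sqrt(((observed - expected) ** 2).mean()))
    return {"table": table, "slope": slope, "r_squared": r2,
            "tpr": tpr, "tnr": tnr, "rmse": rmse}


def loq_flag(counts: pd.Series, loq: float) -> tuple[pd.Series, float]:
    """Flag features above/below the LOQ; report the fraction above."""
    if len(counts) == 0:
        logger.warning("loq_flag called with no features")
        return pd.Series(dtype=bool), float("nan")
    flags = counts > loq
    return flags, float(flags.mean())
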