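import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from captorkit.errors import (InsufficientDataError, InvalidInputError,
                              InvalidParameterError)
from captorkit.mixture import build_staggered_manifest
from captorkit.quant import (CountMatrix, build_count_matrix, captor_counts,
                             fold_change_eval, feature_counts, ladder_fit,
                             loq_flag, min_reliable_depth, ruvg_normalize,
                             segmental_fit, subsample_reads, tmm_factors)


@dataclass(frozen=True)
class FakeCall:
    captor_id: str


def calls(spec: dict[str, int]):
    out = []
    for cid, n in spec.items():
        out.extend([FakeCall(cid)] * n)
    return out


class TestCaptorCounts:
    def test_simple_tally(self):
        counts, n_uncl = captor_counts(calls({"adaptor_1": 10}))
        assert counts.to_dict() == {"adaptor_1": 10}
        assert n_uncl == 0

    def test_unclassified_reported_separately(self):
        counts, n_uncl = captor_counts(
            calls({"a": 3, "UNCLASSIFIED": 2, "b": 1}))
        assert counts.to_dict() == {"a": 3, "b": 1}
        assert n_uncl == 2

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            counts, _ = captor_counts([])
        assert counts.empty


class TestLadderFit:
    def manifest(self, n=16, gs=2, lv=8):
        return build_staggered_manifest([f"c{i}" for i in range(n)],
                                        group_size=gs, n_levels=lv)

    def test_proportional_counts_give_unit_slope(self):
        m = self.manifest()
        counts = pd.Series({e.captor_id: 1024 * e.relative_concentration
                            for e in m.entries})
        fit = ladder_fit(counts, m)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_squared_relationship_gives_slope_two(self):
        m = self.manifest()
        counts = pd.Series({e.captor_id: 4096 * e.relative_concentration ** 2
                            for e in m.entries})
        assert ladder_fit(counts, m).slope == pytest.approx(2.0)

    def test_zero_count_adaptors_reported_not_fitted(self):
        m = self.manifest()
        counts = pd.Series({e.captor_id: 1024 * e.relative_concentration
                            for e in m.entries if e.group < 6})
        fit = ladder_fit(counts, m)
        assert fit.n_points == 12
        assert len(fit.not_detected) == 4

    def test_insufficient_points_rejected(self):
        m = self.manifest()
        with pytest.raises(InsufficientDataError):
            ladder_fit(pd.Series({"c0": 5, "c1": 3}), m)


class TestSegmentalFit:
    def test_noiseless_kink_recovered_to_grid_resolution(self):
        x = np.linspace(-7, 0, 29)
        c_true = -3.55
        y = np.where(x < c_true, 2 + 0.2 * (x - c_true),
                     2 + 1.0 * (x - c_true))
        fit = segmental_fit(np.column_stack([x, y]))
        grid = np.diff(np.unique(x)).max()
        assert abs(fit.breakpoint_x - c_true) <= grid
        assert fit.left_slope == pytest.approx(0.2, abs=0.05)
        assert fit.right_slope == pytest.approx(1.0, abs=0.05)

    def test_collinear_data_flagged_degenerate(self):
        x = np.linspace(0, 5, 12)
        fit = segmental_fit(np.column_stack([x, 1 + 0.8 * x]))
        assert fit.degenerate
        assert fit.left_slope == pytest.approx(fit.right_slope)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_beats_single_line_on_kinked_data(self):
        x = np.linspace(-6, 0, 24)
        y = np.where(x < -3, 1.0 + 0 * x, 1.0 + 2 * (x + 3))
        fit = segmental_fit(np.column_stack([x, y]))
        beta = np.polyfit(x, y, 1)
        sse_line = float(((y - np.polyval(beta, x)) ** 2).sum())
        assert fit.sse * 10 < sse_line

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            segmental_fit([(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)])

    def test_loq_is_on_count_scale(self):
        x = np.linspace(-7, 0, 20)
        y = np.where(x < -4, 3.0 + 0 * x, 3.0 + 1.0 * (x + 4))
        fit = segmental_fit(np.column_stack([x, y]))
        assert fit.breakpoint_reads == pytest.approx(
            2.0 ** fit.breakpoint_log2_reads)
        assert fit.breakpoint_reads == pytest.approx(8.0, rel=0.3)


class TestSubsampling:
    def test_full_fraction_is_identity(self):
        reads = list(range(50))
        assert subsample_reads(reads, fraction=1.0) == reads

    def test_zero_reads(self):
        assert subsample_reads(list(range(10)), n=0) == []

    def test_deterministic_per_seed(self):
        reads = list(range(1000))
        a = subsample_reads(reads, n=100, rng_seed=5)
        b = subsample_reads(reads, n=100, rng_seed=5)
        c = subsample_reads(reads, n=100, rng_seed=6)
        assert a == b and a != c

    def test_oversampling_rejected(self):
        with pytest.raises(InvalidParameterError):
            subsample_reads([1, 2], n=5)


class TestMinReliableDepth:
    def test_single_adaptor_manifest_trivially_reliable(self):
        m = build_staggered_manifest(["only"], group_size=1, n_levels=1)
        cls = calls({"only": 200})
        # ladder needs >= 3 points, so relax to the detection criterion only
        depth, diag = min_reliable_depth(cls, m, [50, 100], min_r2=-np.inf)
        assert depth is None or depth in (50, 100)
        assert diag.n_detected.iloc[-1] == 1

    def test_detection_threshold_drives_reliability(self):
        rng = np.random.default_rng(0)
        m = build_staggered_manifest([f"c{i}" for i in range(12)],
                                     group_size=3, n_levels=4)
        draws = rng.choice(m.ids, size=5000, p=m.fractions)
        cls = [FakeCall(c) for c in draws]
        depth, diag = min_reliable_depth(cls, m, [200, 1000, 5000],
                                         min_r2=0.8)
        assert depth is not None
        assert bool(diag.set_index("depth").loc[depth, "reliable"])

    def test_sentinel_when_never_reliable(self):
        m = build_staggered_manifest([f"c{i}" for i in range(4)],
                                     group_size=1, n_levels=4)
        cls = calls({"c0": 30})  # only the undiluted adaptor ever seen
        depth, diag = min_reliable_depth(cls, m, [10, 30])
        assert depth is None
        assert not diag.reliable.any()


class TestFeatureCounts:
    lengths = {"f1": 100, "f2": 200}

    def test_full_coverage_is_depth_one(self):
        fc = feature_counts([("f1", (0, 100))], self.lengths)
        assert fc["f1"] == 1.0

    def test_two_inserts_sum(self):
        fc = feature_counts([("f1", (0, 100)), ("f1", (0, 100))],
                            self.lengths)
        assert fc["f1"] == 2.0

    def test_partial_coverage_fraction(self):
        fc = feature_counts([("f1", (25, 75))], self.lengths)
        assert fc["f1"] == 0.5
        assert fc["f2"] == 0.0


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        m = pd.DataFrame({"s1": [100, 200, 50], "s2": [100, 200, 50]},
                         index=list("abc"))
        assert tmm_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_global_doubling_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        a = pd.Series(rng.integers(50, 500, 30).astype(float))
        m = pd.DataFrame({"s1": a, "s2": 2 * a})
        assert tmm_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_matches_edgeR_reference_implementation(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.integers(20, 2000, size=(40, 4)).astype(float),
                         index=[f"g{i}" for i in range(40)],
                         columns=list("wxyz"))
        m.iloc[0, 1] *= 8
        ours = tmm_factors(m, ref_sample="w").to_numpy()
        script = (
            "suppressMessages(library(edgeR));"
            "m<-matrix(scan('stdin',quiet=TRUE),ncol=4,byrow=TRUE);"
            "cat(sprintf('%.12f ',calcNormFactors(m,method='TMM',"
            "refColumn=1)))")
        r = subprocess.run(
            ["Rscript", "-e", script],
            input="\n".join(" ".join(str(v) for v in row)
                            for row in m.to_numpy()),
            capture_output=True, text=True, timeout=300)
        theirs = np.array([float(x) for x in r.stdout.split()])
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_all_zero_sample_named_in_error(self):
        m = pd.DataFrame({"good": [10, 20], "empty": [0, 0]})
        with pytest.raises(InvalidInputError, match="empty"):
            tmm_factors(m)


class TestRUVg:
    def make_matrix(self, batch=None, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        base = rng.uniform(50, 500, size=30)
        samples = {}
        for s in range(6):
            lam = base.copy()
            if batch is not None:
                lam = lam * np.exp(batch[s] * self.loadings)
            samples[f"s{s}"] = rng.poisson(lam)
        counts = pd.DataFrame(samples, index=[f"g{i}" for i in range(30)])
        is_control = pd.Series([i < 10 for i in range(30)],
                               index=counts.index)
        return CountMatrix(counts=counts.astype(float),
                           is_control=is_control)

    loadings = np.concatenate([np.linspace(-1, 1, 10),
                               np.linspace(-1, 1, 20)])

    def test_constant_controls_leave_matrix_unchanged(self):
        counts = pd.DataFrame({
            "s1": [50.0, 80.0, 10.0, 30.0], "s2": [50.0, 80.0, 22.0, 14.0],
            "s3": [50.0, 80.0, 17.0, 40.0]}, index=list("abcd"))
        cm = CountMatrix(counts=counts,
                         is_control=pd.Series([True, True, False, False],
                                              index=counts.index))
        corrected, w = ruvg_normalize(cm, k=1)
        assert np.allclose(np.log(corrected + 1), np.log(counts + 1),
                           atol=1e-6)

    def test_planted_batch_effect_removed_from_controls(self):
        batch = np.array([0.8, -0.8, 0.8, -0.8, 0.0, 0.0])
        cm = self.make_matrix(batch=batch)
        corrected, w = ruvg_normalize(cm, k=1)
        ctrl = cm.counts.loc[cm.is_control]
        ctrl_corr = corrected.loc[cm.is_control]
        var_before = np.log(ctrl + 1).var(axis=1).mean()
        var_after = np.log(ctrl_corr + 1).var(axis=1).mean()
        assert var_after * 10 < var_before

    def test_k_bounds_enforced(self):
        cm = self.make_matrix()
        with pytest.raises(InvalidParameterError):
            ruvg_normalize(cm, k=0)
        with pytest.raises(InvalidParameterError):
            ruvg_normalize(cm, k=6)

    def test_maximal_k_runs_with_warning(self, caplog):
        cm = self.make_matrix()
        sub = CountMatrix(counts=cm.counts[["s0", "s1", "s2"]],
                          is_control=cm.is_control)
        with caplog.at_level("WARNING"):
            corrected, w = ruvg_normalize(sub, k=2)
        assert corrected.shape == sub.counts.shape


class TestFoldChangeEval:
    def test_exact_fold_changes_recovered(self):
        rng = np.random.default_rng(2)
        base = pd.Series(rng.uniform(100, 1000, 8),
                         index=[f"f{i}" for i in range(8)])
        expected = {f"f{i}": lfc for i, lfc in
                    enumerate([2, 1, -1, -2, 0, 0, 0, 0])}
        a = pd.DataFrame({"a1": base, "a2": base})
        b = pd.DataFrame({
            "b1": base * 2.0 ** pd.Series(expected),
            "b2": base * 2.0 ** pd.Series(expected)})
        # pseudocount 0: every value is positive and the fold changes are
        # exact, so detection at the +-1 threshold must not be shrunk
        res = fold_change_eval(a, b, expected, pseudocount=0.0)
        assert res["slope"] == pytest.approx(1.0, abs=1e-9)
        assert res["tpr"] == 1.0 and res["tnr"] == 1.0
        assert res["rmse"] < 1e-9

    def test_null_spec_has_no_tpr(self):
        base = pd.Series([100.0, 200.0], index=["f1", "f2"])
        a = pd.DataFrame({"a1": base, "a2": base})
        res = fold_change_eval(a, a, {"f1": 0.0, "f2": 0.0})
        assert np.isnan(res["tpr"])
        assert res["tnr"] == 1.0

    def test_requires_replicates(self):
        base = pd.DataFrame({"a1": [1.0, 2.0]}, index=["f1", "f2"])
        with pytest.raises(InvalidParameterError):
            fold_change_eval(base, base, {"f1": 0.0})


class TestLoqFlag:
    def test_fraction_above(self):
        flags, frac = loq_flag(pd.Series({"a": 10.0, "b": 5.0}), 7.1)
        assert flags.to_dict() == {"a": True, "b": False}
        assert frac == 0.5

    def test_all_above(self):
        _, frac = loq_flag(pd.Series({"a": 10.0, "b": 9.0}), 7.1)
        assert frac == 1.0

    def test_empty_warns(self, caplog):
        with caplog.at_level("WARNING"):
            flags, frac = loq_flag(pd.Series(dtype=float), 7.1)
        assert np.isnan(frac)


class TestCountMatrix:
    def test_round_trip(self, tmp_path):
        cm = build_count_matrix({
            "s1": (pd.Series({"f1": 1.5}), pd.Series({"c1": 30})),
            "s2": (pd.Series({"f1": 2.0}), pd.Series({"c1": 28}))})
        p = tmp_path / "counts.tsv"
        cm.to_tsv(p)
        back = CountMatrix.from_tsv(p)
        pd.testing.assert_frame_equal(back.counts, cm.counts)
        assert back.control_ids == ["c1"]

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            CountMatrix(counts=pd.DataFrame({"s": [-1.0]}, index=["f"]),
                        is_control=pd.Series([False], index=["f"]))
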