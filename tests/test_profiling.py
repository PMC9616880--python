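import numpy as np
import pandas as pd
import pytest
from scipy import stats

import captorkit as ck
from captorkit.align import EventProfile, profile_reads_to_reference
from captorkit.design import Adaptor
from captorkit.errors import ConsistencyError, InvalidInputError
from captorkit.profiling import (CLASSES, compare_tables, kmer_table,
                                 pore_time_summary, profile_correlation,
                                 profile_rates, restrict_to_variants,
                                 subtract_profiles)
from captorkit.simulate import simulate_reads_from_reference

from .conftest import random_dna


def make_events(ref, n_match, n_mismatch=None, n_insertion=None,
                n_deletion=None):
    n = len(ref)
    zeros = np.zeros(n, dtype=np.int64)
    return EventProfile("x", ref,
                        np.asarray(n_match, dtype=np.int64),
                        zeros.copy() if n_mismatch is None
                        else np.asarray(n_mismatch, dtype=np.int64),
                        zeros.copy() if n_insertion is None
                        else np.asarray(n_insertion, dtype=np.int64),
                        zeros.copy() if n_deletion is None
                        else np.asarray(n_deletion, dtype=np.int64))


def binomial_profile(ref, rates, depth, rng, extra_mismatch=None):
    """Event profile drawn binomially from per-position per-class rates."""
    n = len(ref)
    rm = rates["mismatch"].copy()
    if extra_mismatch is not None:
        rm = np.minimum(rm + extra_mismatch, 1.0)
    n_mis = rng.binomial(depth, rm)
    n_del = rng.binomial(depth, rates["deletion"])
    n_ins = rng.binomial(depth, rates["insertion"])
    n_match = depth - n_mis - n_del
    ev = make_events(ref, n_match, n_mis, n_ins, n_del)
    return profile_rates(ev, min_depth=10)


class TestProfileRates:
    def test_all_match_gives_zero_rates(self):
        p = profile_rates(make_events("ACGT" * 5, [20] * 20))
        assert np.all(p.r_total == 0)

    def test_rate_arithmetic(self):
        ev = make_events("ACGT", [18, 20, 20, 20], [2, 0, 0, 0])
        p = profile_rates(ev)
        assert p.r_mismatch[0] == pytest.approx(0.1)

    def test_low_depth_positions_absent(self):
        ev = make_events("ACGT", [5, 20, 20, 20])
        p = profile_rates(ev, min_depth=10)
        assert np.isnan(p.r_mismatch[0]) and not np.isnan(p.r_mismatch[1])


def synthetic_adaptor(var, idx=0):
    return Adaptor(f"A{idx}", "A" * 30, var, "T" * 30)


class TestKmerTable:
    def test_uniform_rate_propagates(self):
        a = synthetic_adaptor(random_dna(30, 1))
        ev = make_events(a.full_sequence, [19] * 90, [1] * 90)
        tab = kmer_table({a.id: profile_rates(ev)}, [a])
        assert np.allclose(tab.mean_r_mismatch, 0.05)
        assert np.allclose(tab.mean_r_total, 0.05)

    def test_thirty_nt_region_yields_25_windows(self):
        a = synthetic_adaptor(random_dna(30, 2))
        ev = make_events(a.full_sequence, [20] * 90)
        tab = kmer_table({a.id: profile_rates(ev)}, [a])
        assert tab.n_instances.sum() == 25

    def test_shared_kmer_averages_across_instances(self):
        # same variable region in two adaptors, one at rate 0.02, one at 0.04
        var = random_dna(30, 3)
        a, b = synthetic_adaptor(var, 0), synthetic_adaptor(var, 1)
        ev_a = make_events(a.full_sequence, [98] * 90, [2] * 90)
        ev_b = make_events(b.full_sequence, [96] * 90, [4] * 90)
        tab = kmer_table({a.id: profile_rates(ev_a),
                          b.id: profile_rates(ev_b)}, [a, b])
        assert np.allclose(tab.mean_r_mismatch, 0.03)
        assert (tab.n_instances >= 2).all()

    def test_annotations_are_pure_functions_of_kmer(self):
        a = synthetic_adaptor("GGGGGGCATCATCATCATCATACGTACGTA")
        ev = make_events(a.full_sequence, [20] * 90)
        tab = kmer_table({a.id: profile_rates(ev)}, [a]).set_index("kmer")
        assert tab.loc["GGGGGG", "gc_count"] == 6
        assert tab.loc["GGGGGG", "max_homopolymer_run"] == 6

    def test_missing_profile_rejected(self, panel):
        with pytest.raises(ConsistencyError):
            kmer_table({}, panel[:1])


class TestCompareTables:
    def make_table(self, scale=1.0):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.01, 0.1, size=20)
        return pd.DataFrame({
            "kmer": [random_dna(6, i + 50) for i in range(20)],
            "mean_r_mismatch": base * scale,
            "mean_r_insertion": base * 0.5 * scale,
            "mean_r_deletion": base * 0.7 * scale,
            "mean_r_total": base * 2.2 * scale})

    def test_self_comparison_is_zero(self):
        t = self.make_table()
        _, summary = compare_tables(t, t)
        assert all(summary[c] == 0 for c in CLASSES)

    def test_uniform_scaling_gives_constant_relative_difference(self):
        _, summary = compare_tables(self.make_table(), self.make_table(1.1))
        for c in CLASSES:
            assert summary[c] == pytest.approx(100 * 0.1 / 1.05, rel=1e-9)

    def test_replicate_difference_shrinks_with_depth(self, panel,
                                                     error_model):
        sub = panel[:6]
        tabs = {}
        for depth in (150, 1500):
            profs = {}
            for k, a in enumerate(sub):
                reads = simulate_reads_from_reference(
                    a.full_sequence, depth, error_model, rng_seed=k)
                profs[a.id] = profile_rates(
                    profile_reads_to_reference(a.id, a.full_sequence, reads))
            tabs[depth] = kmer_table(profs, sub)
        # replicate with a different seed at each depth
        tabs2 = {}
        for depth in (150, 1500):
            profs = {}
            for k, a in enumerate(sub):
                reads = simulate_reads_from_reference(
                    a.full_sequence, depth, error_model, rng_seed=1000 + k)
                profs[a.id] = profile_rates(
                    profile_reads_to_reference(a.id, a.full_sequence, reads))
            tabs2[depth] = kmer_table(profs, sub)
        _, shallow = compare_tables(tabs[150], tabs2[150])
        _, deep = compare_tables(tabs[1500], tabs2[1500])
        assert deep["total"] < shallow["total"]


class TestPoreTimeSummary:
    def test_constant_error_gives_flat_series(self):
        df = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(40)],
            "channel": [1] * 40,
            "start_time": np.linspace(0, 7000, 40),
            "per_read_error": [0.05] * 40})
        binned, per_channel = pore_time_summary(df, time_bin=3600)
        assert np.allclose(binned.mean_error, 0.05)
        assert per_channel.bin_ratio.iloc[0] == pytest.approx(1.0)

    def test_channel_means_reflect_multipliers(self, panel, manifest,
                                               sample_refs, error_model):
        pores = ck.PoreModel((
            ck.simulate.PoreChannel(1, error_multiplier=1.0),
            ck.simulate.PoreChannel(2, error_multiplier=3.0)))
        reads, truth = ck.simulate_library(
            panel, manifest, sample_refs, error_model, pores,
            ck.SimConfig(n_reads=3000, rng_seed=5))
        truth["per_read_error"] = (truth.n_sub + truth.n_ins
                                   + truth.n_del) / 330.0
        _, per_channel = pore_time_summary(truth, time_bin=3600)
        m = per_channel.set_index("channel").mean_error
        assert m[2] / m[1] == pytest.approx(3.0, rel=0.15)

    def test_no_channel_metadata_warns_and_returns_empty(self, caplog):
        df = pd.DataFrame({"read_id": ["r"], "channel": [np.nan],
                           "start_time": [0.0], "per_read_error": [0.1]})
        with caplog.at_level("WARNING"):
            binned, per_channel = pore_time_summary(df)
        assert binned.empty and per_channel.empty


def shared_rate_vectors(n, rng):
    rates = {
        "mismatch": np.clip(0.02 + rng.normal(0, 0.01, n), 0.001, 0.3),
        "insertion": np.clip(0.012 + rng.normal(0, 0.008, n), 0.001, 0.3),
        "deletion": np.clip(0.018 + rng.normal(0, 0.01, n), 0.001, 0.3)}
    return rates


class TestSubtraction:
    def test_subtracting_self_zeroes_everything(self):
        rng = np.random.default_rng(1)
        ref = random_dna(100, 1)
        rates = shared_rate_vectors(100, rng)
        p = binomial_profile(ref, rates, 500, np.random.default_rng(2))
        rep = subtract_profiles(p, p)
        for cls in CLASSES:
            assert np.nanmax(rep.corrected_rates[cls]) == 0.0

    def test_variant_excess_survives_subtraction(self):
        rng = np.random.default_rng(3)
        ref = random_dna(200, 2)
        rates = shared_rate_vectors(200, rng)
        extra = np.zeros(200)
        extra[70] = 0.4
        control = binomial_profile(ref, rates, 2000,
                                   np.random.default_rng(4))
        sample = binomial_profile(ref, rates, 2000,
                                  np.random.default_rng(5),
                                  extra_mismatch=extra)
        rep = subtract_profiles(sample, control)
        assert rep.corrected_rates["mismatch"][70] == pytest.approx(0.4,
                                                                    abs=0.05)
        others = np.delete(rep.corrected_rates["mismatch"], 70)
        assert np.nanmedian(others) < 0.01

    def test_correction_clamps_at_zero(self):
        ref = "ACGTACGTAC"
        lo = profile_rates(make_events(ref, [100] * 10))
        hi = profile_rates(make_events(ref, [90] * 10, [10] * 10))
        rep = subtract_profiles(lo, hi)
        assert np.all(rep.corrected_rates["mismatch"] == 0)

    def test_subtraction_idempotent_after_first_pass(self):
        rng = np.random.default_rng(6)
        ref = random_dna(80, 3)
        rates = shared_rate_vectors(80, rng)
        sample = binomial_profile(ref, rates, 400, np.random.default_rng(7))
        control = binomial_profile(ref, rates, 400, np.random.default_rng(8))
        first = subtract_profiles(sample, control)
        # re-apply the control to the corrected rates
        second = {cls: np.maximum(first.corrected_rates[cls]
                                  - first.control_rates[cls], 0.0)
                  for cls in CLASSES}
        for cls in CLASSES:
            corrected = first.corrected_rates[cls]
            assert np.allclose(second[cls],
                               np.maximum(corrected
                                          - first.control_rates[cls], 0.0))

    def test_length_mismatch_rejected(self):
        a = profile_rates(make_events("ACGT", [20] * 4))
        b = profile_rates(make_events("ACGTA", [20] * 5))
        with pytest.raises(ConsistencyError):
            subtract_profiles(a, b)


class TestRestrictToVariants:
    def _report(self):
        rng = np.random.default_rng(9)
        ref = random_dna(50, 4)
        rates = shared_rate_vectors(50, rng)
        s = binomial_profile(ref, rates, 300, np.random.default_rng(10))
        c = binomial_profile(ref, rates, 300, np.random.default_rng(11))
        return subtract_profiles(s, c)

    def test_full_mask_preserves_summary(self):
        rep = self._report()
        full = restrict_to_variants(rep, np.arange(50))
        assert full.summary() == rep.summary()

    def test_single_position_mask(self):
        rep = self._report()
        one = restrict_to_variants(rep, np.array([7]))
        s = one.summary()
        assert s["mismatch"]["median_before"] \
            == pytest.approx(rep.sample_rates["mismatch"][7])

    def test_empty_mask_warns(self, caplog):
        rep = self._report()
        with caplog.at_level("WARNING"):
            masked = restrict_to_variants(rep, np.array([], dtype=int))
            out = masked.summary()
        assert np.isnan(out["total"]["median_before"])


class TestProfileCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(12)
        ref = random_dna(60, 5)
        p = binomial_profile(ref, shared_rate_vectors(60, rng), 400,
                             np.random.default_rng(13))
        corr = profile_correlation(p, p)
        assert all(corr[c] == pytest.approx(1.0) for c in CLASSES)

    def test_zero_variance_control_undefined(self, caplog):
        ref = "ACGTACGTACGT"
        const = profile_rates(make_events(ref, [95] * 12, [5] * 12))
        varying = profile_rates(make_events(
            ref, [100 - i for i in range(12)], list(range(12))))
        with caplog.at_level("WARNING"):
            corr = profile_correlation(varying, const)
        assert np.isnan(corr["mismatch"])

    def test_correlation_rises_with_shared_systematic_component(self):
        ref = random_dna(150, 6)
        out = {}
        for sd in (0.002, 0.03):
            rng = np.random.default_rng(14)
            shared = np.clip(0.03 + rng.normal(0, sd, 150), 0.002, 0.4)
            rates = {"mismatch": shared, "insertion": shared * 0.5,
                     "deletion": shared * 0.6}
            s = binomial_profile(ref, rates, 1500, np.random.default_rng(15))
            c = binomial_profile(ref, rates, 1500, np.random.default_rng(16))
            out[sd] = profile_correlation(s, c)["mismatch"]
        assert 0 < out[0.002] < out[0.03] <= 1


class TestGcAndHomopolymerTrends:
    def test_recovered_table_shows_positive_gc_and_run_trends(
            self, deep_library, panel):
        """The generator's GC and homopolymer slopes are positive, so the
        recovered per-6-mer error table must rise across GC strata and
        homopolymer-run strata (Spearman trend > 0)."""
        tab = kmer_table(deep_library["profiles"], panel)
        rho_gc = stats.spearmanr(tab.gc_count, tab.mean_r_total).statistic
        rho_run = stats.spearmanr(tab.max_homopolymer_run,
                                  tab.mean_r_total).statistic
        assert rho_gc > 0
        assert rho_run > 0


class TestInputValidation:
    def test_disjoint_tables_rejected(self):
        t1 = pd.DataFrame({"kmer": ["AAAAAA"], "mean_r_mismatch": [0.1],
                           "mean_r_insertion": [0.1],
                           "mean_r_deletion": [0.1], "mean_r_total": [0.3]})
        t2 = t1.assign(kmer=["CCCCCC"])
        with pytest.raises(InvalidInputError):
            compare_tables(t1, t2)
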