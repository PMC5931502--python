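"""Poisson occupancy, allele dropout, error rates, VAF, distribution test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from sdgeno.calibration import apply_bleedthrough_correction
from sdgeno.classify import classify_array, qc_counts
from sdgeno.stats import (
    HetArrayCalls,
    compare_occupancy,
    compute_vaf,
    estimate_ado,
    estimate_lambda,
    expected_occupancy,
    expected_zygosity_under_het,
    false_allele_rate,
    fpr_fnr,
    het_array_calls_from_table,
    occupancy_from_negative_fraction,
    poisson_pmf,
    zygosity_distribution_test,
)
from sdgeno.synthetic import SimulationConfig, control_config, simulate_array
from sdgeno.types import TemplateKind, ValidationError


class TestPoisson:
    @pytest.mark.parametrize(
        "k,lam,expected",
        [
            (0, 1.0, math.exp(-1)),
            (0, 0.0, 1.0),
            (2, 0.5, 0.5**2 * math.exp(-0.5) / 2),
        ],
    )
    def test_pmf_values(self, k, lam, expected):
        assert poisson_pmf(k, lam) == pytest.approx(expected, rel=1e-12)

    def test_pmf_rejects_negative(self):
        with pytest.raises(ValidationError):
            poisson_pmf(-1, 1.0)
        with pytest.raises(ValidationError):
            poisson_pmf(0, -1.0)

    @pytest.mark.parametrize(
        "f0,lam",
        [(math.exp(-1), 1.0), (1.0, 0.0), (0.5, math.log(2))],
    )
    def test_lambda_from_negative_fraction(self, f0, lam):
        assert estimate_lambda(f0) == pytest.approx(lam, rel=1e-12)

    def test_lambda_domain(self):
        with pytest.raises(ValidationError):
            estimate_lambda(0.0)
        with pytest.raises(ValidationError):
            estimate_lambda(1.1)

    def test_expected_occupancy_values(self):
        est = expected_occupancy(1024, 1.0)
        assert est.expected_single == pytest.approx(1024 * math.exp(-1), rel=1e-12)
        assert est.expected_multi == pytest.approx(1024 * (1 - 2 * math.exp(-1)), rel=1e-12)
        zero = expected_occupancy(1024, 0.0)
        assert (zero.expected_zero, zero.expected_single, zero.expected_multi) == (1024.0, 0.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(lam=st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    def test_occupancy_probabilities_partition(self, lam):
        est = expected_occupancy(1000, lam)
        assert est.p0 + est.p1 + est.p_gt1 == pytest.approx(1.0, abs=1e-12)

    def test_lambda_round_trip_from_simulation(self):
        n = 100_000
        lam = 0.7
        cfg = SimulationConfig(
            occupancy_lambda=lam,
            doublet_excess=0.0,
            fill_failure_rate=0.0,
            wells_per_array=n,
            seed=53,
        )
        _, truth = simulate_array(cfg)
        f0 = (truth["true_event_count"] == 0).mean()
        lam_hat = estimate_lambda(f0)
        # delta method: SE(lam_hat) = sqrt((1 - p0) / (n p0))
        se = math.sqrt((1 - math.exp(-lam)) / (n * math.exp(-lam)))
        assert abs(lam_hat - lam) < 3 * se


class TestOccupancyComparison:
    def test_exact_expectation_gives_unit_ratios(self):
        est = expected_occupancy(10_000, 0.5)
        observed = (round(est.expected_zero), round(est.expected_single), 0)
        observed = (observed[0], observed[1], 10_000 - observed[0] - observed[1])
        comp = compare_occupancy(observed, est)
        assert comp.ratio_single == pytest.approx(1.0, rel=0.01)
        assert comp.ratio_multi == pytest.approx(1.0, rel=0.03)

    def test_doublet_excess_detected(self):
        n = 10_000
        cfg = SimulationConfig(
            occupancy_lambda=0.25,
            doublet_excess=0.3,
            fill_failure_rate=0.0,
            wells_per_array=n,
            seed=59,
        )
        _, truth = simulate_array(cfg)
        c = truth["true_event_count"].to_numpy()
        obs = ((c == 0).sum(), (c == 1).sum(), (c > 1).sum())
        est = occupancy_from_negative_fraction(n, obs[0] / n)
        comp = compare_occupancy(obs, est)
        assert comp.ratio_multi > 1.0
        assert comp.p_doublet_excess < 0.01

    def test_type_one_error_controlled_without_excess(self):
        # under pure Poisson loading the excess test should rarely fire
        n = 10_000
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = rng.poisson(0.25, n)
            obs = ((c == 0).sum(), (c == 1).sum(), (c > 1).sum())
            est = occupancy_from_negative_fraction(n, obs[0] / n)
            comp = compare_occupancy(obs, est)
            if comp.p_doublet_excess < 0.01:
                rejections += 1
        assert rejections <= 5


def _negative_fraction_for_expected_multi(total_wells, expected_multi):
    """Invert total * P(>1; lambda) = expected_multi for the zero fraction."""

    def f(lam):
        return total_wells * (1 - math.exp(-lam) - lam * math.exp(-lam)) - expected_multi

    lam = brentq(f, 1e-9, 5.0)
    return math.exp(-lam)


class TestADO:
    def test_no_dropout_gives_zero(self):
        f0 = _negative_fraction_for_expected_multi(1000, 5.0)
        rec = HetArrayCalls("a", n_wt=0, n_het=100, n_mut=0, negative_fraction=f0, total_wells=1000)
        est = estimate_ado([rec])
        assert est.ado_wt == 0.0 and est.ado_mut == 0.0

    def test_conservative_denominator_arithmetic(self):
        # 104 genotyped, expected 4 multi-plasmid wells -> denominator 100
        f0 = _negative_fraction_for_expected_multi(1000, 4.0)
        rec = HetArrayCalls("a", n_wt=5, n_het=90, n_mut=9, negative_fraction=f0, total_wells=1000)
        est = estimate_ado([rec])
        assert est.ado_mut == pytest.approx(0.05, abs=1e-9)
        assert est.ado_wt == pytest.approx(0.09, abs=1e-9)
        assert est.expected_multi_per_array[0] == pytest.approx(4.0, abs=1e-6)

    def test_overloaded_array_rejected(self):
        f0 = _negative_fraction_for_expected_multi(1000, 200.0)
        rec = HetArrayCalls("a", n_wt=2, n_het=50, n_mut=3, negative_fraction=f0, total_wells=1000)
        with pytest.raises(ValidationError, match="over-loaded"):
            estimate_ado([rec])

    def test_recovery_at_single_copy_loading(self, control_setup):
        """Mean ADO estimates over 40 replicate array sets stay within 0.5
        percentage points of the generator truth (5.4% / 8.5%)."""
        cals, bleed = control_setup["calibrations"], control_setup["bleed"]
        wt_means, mut_means = [], []
        for rep in range(40):
            records = []
            for i in range(6):
                arr, _ = simulate_array(control_config(TemplateKind.HET_PLASMID, seed=3000 + rep * 6 + i))
                table = classify_array(apply_bleedthrough_correction(arr, bleed), cals)
                records.append(het_array_calls_from_table(table, arr.array_id))
            est = estimate_ado(records)
            wt_means.append(est.ado_wt)
            mut_means.append(est.ado_mut)
        assert abs(np.mean(wt_means) - 0.054) < 0.005
        assert abs(np.mean(mut_means) - 0.085) < 0.005

    def test_multi_occupancy_correction_reduces_bias(self, control_setup):
        """At lambda=0.5 (multi-copy contamination) the Poisson-corrected
        estimator is less biased than the uncorrected one."""
        cals, bleed = control_setup["calibrations"], control_setup["bleed"]
        records = []
        for i in range(12):
            arr, _ = simulate_array(
                control_config(TemplateKind.HET_PLASMID, seed=5000 + i, occupancy_lambda=0.5)
            )
            table = classify_array(apply_bleedthrough_correction(arr, bleed), cals)
            records.append(het_array_calls_from_table(table, arr.array_id))
        corrected = estimate_ado(records, correct_multi=True)
        uncorrected = estimate_ado(records, correct_multi=False)
        assert abs(corrected.ado_mut - 0.085) < abs(uncorrected.ado_mut - 0.085)
        assert abs(corrected.ado_wt - 0.054) < abs(uncorrected.ado_wt - 0.054)


class TestRates:
    @pytest.mark.parametrize(
        "n_false,n_total,expected_pct",
        [(2, 610, 0.3), (2, 885, 0.2), (0, 100, 0.0)],
    )
    def test_false_allele_rate(self, n_false, n_total, expected_pct):
        assert round(100 * false_allele_rate(n_false, n_total), 1) == expected_pct

    def test_false_allele_rate_domain(self):
        with pytest.raises(ValidationError):
            false_allele_rate(1, 0)
        with pytest.raises(ValidationError):
            false_allele_rate(5, 4)

    def test_fpr_fnr_arithmetic(self):
        assert fpr_fnr({"FP": 2, "TN": 98, "FN": 0, "TP": 50}) == (0.02, 0.0)

    def test_undefined_denominators_flagged_not_zero(self):
        fpr, fnr = fpr_fnr({"FP": 0, "TN": 0, "FN": 3, "TP": 7})
        assert math.isnan(fpr) and fnr == pytest.approx(0.3)

    def test_fpr_fnr_recovery_from_simulation(self, control_setup):
        cals, bleed = control_setup["calibrations"], control_setup["bleed"]
        cfg = SimulationConfig(
            occupancy_lambda=0.5,
            doublet_excess=0.0,
            fill_failure_rate=0.0,
            fp_rate=0.03,
            fn_rate=0.10,
            count_error_rate=0.0,
            wells_per_array=10_000,
            seed=61,
        )
        arr, _ = simulate_array(cfg)
        table = classify_array(apply_bleedthrough_correction(arr, bleed), cals)
        fpr, fnr = fpr_fnr(qc_counts(table))
        n_empty = (table["cell_count"] == 0).sum()
        n_single = (table["cell_count"] == 1).sum()
        assert abs(fpr - 0.03) < 3 * math.sqrt(0.03 * 0.97 / n_empty)
        assert abs(fnr - 0.10) < 3 * math.sqrt(0.10 * 0.90 / n_single)


class TestVAF:
    @pytest.mark.parametrize(
        "n_mut,n_het,n_wt,expected",
        [(0, 100, 0, 50.0), (10, 0, 0, 100.0), (25, 50, 25, 50.0), (0, 0, 10, 0.0)],
    )
    def test_vaf_values(self, n_mut, n_het, n_wt, expected):
        assert compute_vaf(n_mut, n_het, n_wt) == pytest.approx(expected)

    def test_empty_population_rejected(self):
        with pytest.raises(ValidationError):
            compute_vaf(0, 0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(
        n_mut=st.integers(0, 1000), n_het=st.integers(0, 1000), n_wt=st.integers(0, 1000)
    )
    def test_vaf_bounded(self, n_mut, n_het, n_wt):
        if n_mut + n_het + n_wt == 0:
            return
        vaf = compute_vaf(n_mut, n_het, n_wt)
        assert 0.0 <= vaf <= 100.0

    def test_all_het_cells_with_dropout_shift(self, control_setup):
        """For an all-heterozygous cell population, called VAF sits near
        50% minus the dropout asymmetry (ADO_mut - ADO_wt)/2."""
        cals, bleed = control_setup["calibrations"], control_setup["bleed"]
        cfg = SimulationConfig(
            occupancy_lambda=0.3,
            doublet_excess=0.0,
            fill_failure_rate=0.0,
            fp_rate=0.0,
            fn_rate=0.0,
            count_error_rate=0.0,
            zygosity_mix=(0.0, 1.0, 0.0),
            wells_per_array=100_000,
            seed=67,
        )
        arr, _ = simulate_array(cfg)
        table = classify_array(apply_bleedthrough_correction(arr, bleed), cals)
        from sdgeno.classify import genotype_counts

        g = genotype_counts(table)
        vaf = compute_vaf(g["n_mut"], g["n_het"], g["n_wt"])
        expected_shift = (0.085 - 0.054) / 2 * 100
        assert vaf == pytest.approx(50.0 - expected_shift, abs=1.0)


class TestZygosityDistribution:
    def test_expected_under_het_substitution(self):
        assert expected_zygosity_under_het(0.0, 0.0) == (0.0, 1.0, 0.0)
        p = expected_zygosity_under_het(0.054, 0.085)
        assert p == pytest.approx((0.085, 0.861, 0.054))
        assert sum(p) == pytest.approx(1.0)

    def test_excessive_dropout_rejected(self):
        with pytest.raises(ValidationError):
            expected_zygosity_under_het(0.6, 0.5)

    def test_null_case_large_p(self):
        probs = (0.085, 0.861, 0.054)
        n = 1000
        observed = tuple(round(p * n) for p in probs)
        assert zygosity_distribution_test(observed, probs, seed=1) > 0.5

    def test_strong_mixture_rejected_by_both_methods(self):
        observed = (200, 500, 300)
        probs = (0.085, 0.861, 0.054)
        p_mc = zygosity_distribution_test(observed, probs, seed=1)
        p_chi2 = zygosity_distribution_test(observed, probs, method="chi2")
        assert p_mc < 1e-4  # MC floor is 1/(n_draws + 1)
        assert p_chi2 < 1e-50

    def test_mc_and_chi2_agree_on_moderate_departure(self):
        observed = (60, 890, 50)
        probs = (0.085, 0.861, 0.054)
        p_mc = zygosity_distribution_test(observed, probs, seed=3)
        p_chi2 = zygosity_distribution_test(observed, probs, method="chi2")
        assert p_mc == pytest.approx(p_chi2, rel=0.25)

    def test_zero_probability_floored(self):
        p = zygosity_distribution_test((5, 95, 0), (0.05, 0.95, 0.0), method="chi2")
        assert 0.0 < p <= 1.0
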