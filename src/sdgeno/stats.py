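"""Partition statistics: Poisson occupancy, allele dropout, error rates,
VAF and the zygosity-distribution test.

The loading density lambda (expected events per 8 nL well) is estimated
from the PCR-negative well fraction as lambda = -ln(f0), from which the
expected numbers of single- and multi-event wells follow. Allele-dropout
rates from heterozygous-plasmid arrays use a conservative denominator:
wells expected to hold more than one plasmid are assumed to always type
heterozygous, so their expected count is subtracted from the genotyped
total before dividing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError


# ---------------------------------------------------------------------------
# Poisson occupancy


def poisson_pmf(k: int, lam: float) -> float:
    """P(X = k) for X ~ Poisson(lam): lam^k e^-lam / k!."""
    if k < 0 or lam < 0:
        raise ValidationError("k and lambda must be non-negative")
    return float(sps.poisson.pmf(k, lam))


def estimate_lambda(negative_fraction: float) -> float:
    """Loading density from the PCR-negative well fraction: -ln(f0)."""
    if not 0.0 < negative_fraction <= 1.0:
        raise ValidationError(
            "negative_fraction must be in (0, 1]: lambda is unbounded at 0 and undefined above 1"
        )
    return float(-math.log(negative_fraction))


@dataclass
class OccupancyEstimate:
    """Expected 0 / 1 / >1 event-well counts under Poisson(lambda)."""

    lambda_hat: float
    total_wells: int
    p0: float
    p1: float
    p_gt1: float
    expected_zero: float
    expected_single: float
    expected_multi: float
    observed_counts: tuple[int, int, int] | None = None


def expected_occupancy(total_wells: int, lam: float) -> OccupancyEstimate:
    """Poisson expectations for 0 / 1 / >1 events per well."""
    if total_wells <= 0:
        raise ValidationError("total_wells must be positive")
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    p0 = math.exp(-lam)
    p1 = lam * math.exp(-lam)
    p_gt1 = 1.0 - p0 - p1
    return OccupancyEstimate(
        lambda_hat=float(lam),
        total_wells=int(total_wells),
        p0=p0,
        p1=p1,
        p_gt1=p_gt1,
        expected_zero=total_wells * p0,
        expected_single=total_wells * p1,
        expected_multi=total_wells * p_gt1,
    )


def occupancy_from_negative_fraction(total_wells: int, negative_fraction: float) -> OccupancyEstimate:
    """Expected occupancy with lambda inferred from the zero fraction."""
    return expected_occupancy(total_wells, estimate_lambda(negative_fraction))


@dataclass
class OccupancyComparison:
    """Observed vs Poisson-expected occupancy, with a doublet-excess test."""

    estimate: OccupancyEstimate
    observed_single: int
    observed_multi: int
    ratio_single: float
    ratio_multi: float
    p_doublet_excess: float


def compare_occupancy(observed: tuple[int, int, int], estimate: OccupancyEstimate) -> OccupancyComparison:
    """Compare observed 0/1/>1 counts against a Poisson expectation.

    Reports observed/expected ratios for the single- and multi-event
    categories plus a one-sided exact binomial p-value for multi-event
    excess. The test conditions on the occupied wells: under Poisson
    loading, an occupied well is multi-event with probability
    p_gt1 / (1 - p0), so the observed multi count is tested against
    Binomial(n_occupied, that probability) with the 'greater' alternative.
    """
    n0, n1, nm = (int(v) for v in observed)
    if min(n0, n1, nm) < 0:
        raise ValidationError("counts must be non-negative")
    if n0 + n1 + nm != estimate.total_wells:
        raise ValidationError("observed counts do not sum to the estimate's total wells")
    ratio_single = n1 / estimate.expected_single if estimate.expected_single > 0 else math.nan
    ratio_multi = nm / estimate.expected_multi if estimate.expected_multi > 0 else math.nan
    n_occupied = n1 + nm
    p_occ = 1.0 - estimate.p0
    if n_occupied == 0 or p_occ <= 0:
        p_value = 1.0
    else:
        p_multi_given_occ = min(max(estimate.p_gt1 / p_occ, 0.0), 1.0)
        p_value = float(sps.binomtest(nm, n_occupied, p_multi_given_occ, alternative="greater").pvalue)
    return OccupancyComparison(
        estimate=estimate,
        observed_single=n1,
        observed_multi=nm,
        ratio_single=float(ratio_single),
        ratio_multi=float(ratio_multi),
        p_doublet_excess=p_value,
    )


# ---------------------------------------------------------------------------
# Allele dropout


@dataclass(frozen=True)
class HetArrayCalls:
    """Genotype calls and PCR-negative fraction of one HET-plasmid array."""

    array_id: str
    n_wt: int
    n_het: int
    n_mut: int
    negative_fraction: float
    total_wells: int


@dataclass
class ADOEstimate:
    """Per-allele dropout rates aggregated across array replicates.

    ``ado_wt`` is the rate at which the wild-type allele drops (het
    plasmids typed mutant); ``ado_mut`` the mutant-allele rate (het
    plasmids typed wild-type). Means and SDs are across arrays, matching
    replicate-level error reporting.
    """

    ado_wt: float
    ado_mut: float
    sd_wt: float
    sd_mut: float
    per_array_wt: list[float] = field(default_factory=list)
    per_array_mut: list[float] = field(default_factory=list)
    expected_multi_per_array: list[float] = field(default_factory=list)
    n_calls_total: int = 0


def estimate_ado(arrays: list[HetArrayCalls], correct_multi: bool = True) -> ADOEstimate:
    """Estimate per-allele dropout from heterozygous-plasmid arrays.

    Per array: ADO_mut = n_wt / D and ADO_wt = n_mut / D where the
    conservative denominator D subtracts the Poisson-expected number of
    multi-plasmid wells (assumed always heterozygous) from the genotyped
    total: D = n_wt + n_het + n_mut - total_wells * P(>1 | lambda_hat),
    floored at n_wt + n_mut + 1. With ``correct_multi=False`` the
    uncorrected genotyped total is used instead.
    """
    if not arrays:
        raise ValidationError("at least one heterozygous-plasmid array required")
    per_wt, per_mut, per_multi = [], [], []
    n_calls = 0
    for rec in arrays:
        n_genotyped = rec.n_wt + rec.n_het + rec.n_mut
        if n_genotyped <= 0:
            raise ValidationError(f"array {rec.array_id}: no genotype calls")
        n_calls += n_genotyped
        if correct_multi:
            est = occupancy_from_negative_fraction(rec.total_wells, rec.negative_fraction)
            expected_multi = est.expected_multi
        else:
            expected_multi = 0.0
        denom = n_genotyped - expected_multi
        if denom <= 0:
            raise ValidationError(
                f"array {rec.array_id}: expected multi-occupancy exceeds genotyped total "
                "(array over-loaded for single-copy ADO estimation)"
            )
        denom = max(denom, rec.n_wt + rec.n_mut + 1)
        per_wt.append(rec.n_mut / denom)
        per_mut.append(rec.n_wt / denom)
        per_multi.append(float(expected_multi))
    ddof = 1 if len(arrays) > 1 else 0
    return ADOEstimate(
        ado_wt=float(np.mean(per_wt)),
        ado_mut=float(np.mean(per_mut)),
        sd_wt=float(np.std(per_wt, ddof=ddof)),
        sd_mut=float(np.std(per_mut, ddof=ddof)),
        per_array_wt=per_wt,
        per_array_mut=per_mut,
        expected_multi_per_array=per_multi,
        n_calls_total=n_calls,
    )


def het_array_calls_from_table(call_table: pd.DataFrame, array_id: str = "") -> HetArrayCalls:
    """Build the ADO input record from a classified HET-plasmid array."""
    from .classify import amp_negative_fraction, genotype_counts

    counts = genotype_counts(call_table)
    n_filled = int(call_table["filled"].sum())
    return HetArrayCalls(
        array_id=array_id or str(call_table["array_id"].iloc[0]),
        n_wt=counts["n_wt"],
        n_het=counts["n_het"],
        n_mut=counts["n_mut"],
        negative_fraction=amp_negative_fraction(call_table),
        total_wells=n_filled,
    )


# ---------------------------------------------------------------------------
# Error rates and VAF


def false_allele_rate(n_false: int, n_total: int) -> float:
    """Off-target allele calls divided by total data points."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_false <= n_total:
        raise ValidationError("n_false must lie in [0, n_total]")
    return n_false / n_total


def fpr_fnr(qc: dict[str, int]) -> tuple[float, float]:
    """False-positive and false-negative rates from QC counts.

    FPR = FP / (FP + TN): the fraction of cell-free filled wells that
    amplified. FNR = FN / (FN + TP): the fraction of single-cell wells
    that failed to amplify. An undefined denominator yields NaN (a flagged
    missing value), never zero.
    """
    fp, tn = int(qc.get("FP", 0)), int(qc.get("TN", 0))
    fn, tp = int(qc.get("FN", 0)), int(qc.get("TP", 0))
    if min(fp, tn, fn, tp) < 0:
        raise ValidationError("QC counts must be non-negative")
    fpr = fp / (fp + tn) if (fp + tn) > 0 else math.nan
    fnr = fn / (fn + tp) if (fn + tp) > 0 else math.nan
    return fpr, fnr


def compute_vaf(n_mut: int, n_het: int, n_wt: int) -> float:
    """Variant allele frequency (%) from single-cell genotype counts.

    VAF = (N_mut + N_het / 2) / (N_mut + N_het + N_wt) x 100: mutant
    homozygotes contribute a full mutant allele share, heterozygotes half.
    """
    total = n_mut + n_het + n_wt
    if total <= 0:
        raise ValidationError("at least one genotyped cell required")
    if min(n_mut, n_het, n_wt) < 0:
        raise ValidationError("genotype counts must be non-negative")
    return 100.0 * (n_mut + 0.5 * n_het) / total


# ---------------------------------------------------------------------------
# Zygosity distribution vs the bulk all-heterozygous model


def expected_zygosity_under_het(ado_wt: float, ado_mut: float) -> tuple[float, float, float]:
    """(P_WT, P_HET, P_MUT) a perfect all-heterozygous sample would show.

    Each allele drops independently, so an all-HET population is reported
    wild-type at the mutant-allele dropout rate and mutant at the
    wild-type rate: P_WT = ADO_mut, P_MUT = ADO_wt, P_HET the remainder.
    (Double dropout removes the well to UNCALLED and is not a genotype.)
    """
    if not (0.0 <= ado_wt < 1.0 and 0.0 <= ado_mut < 1.0):
        raise ValidationError("dropout rates must be in [0, 1)")
    if ado_wt + ado_mut >= 1.0:
        raise ValidationError("dropout rates sum to >= 1: no heterozygous calls possible")
    return (ado_mut, 1.0 - ado_mut - ado_wt, ado_wt)


def zygosity_distribution_test(
    observed: tuple[int, int, int],
    expected_probs: tuple[float, float, float],
    method: str = "mc",
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Goodness-of-fit p-value of observed (WT, HET, MUT) counts.

    Default is a seeded Monte-Carlo exact multinomial test: the Pearson
    chi-square statistic of ``n_draws`` multinomial samples under the
    expected probabilities is compared to the observed statistic, with the
    add-one p-value estimate. ``method='chi2'`` uses the asymptotic
    chi-square distribution instead (2 degrees of freedom), appropriate
    when all expected counts are moderate and much faster for repeated
    calibration runs.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.min() < 0 or obs.sum() <= 0:
        raise ValidationError("observed counts must be non-negative with positive total")
    p = np.asarray(expected_probs, dtype=float)
    if p.min() < 0:
        raise ValidationError("expected probabilities must be non-negative")
    p = np.maximum(p, 1e-9)
    p = p / p.sum()
    n = int(obs.sum())
    expected = n * p
    stat_obs = float(((obs - expected) ** 2 / expected).sum())
    if method == "chi2":
        return float(sps.chi2.sf(stat_obs, df=len(p) - 1))
    if method != "mc":
        raise ValidationError(f"unknown method {method!r} (use 'mc' or 'chi2')")
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, p, size=n_draws)
    stat_sim = ((sims - expected) ** 2 / expected).sum(axis=1)
    # add-one estimator: observed data counts as one draw
    return float((1 + np.count_nonzero(stat_sim >= stat_obs - 1e-12)) / (n_draws + 1))
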