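# Methods

This note documents the models, estimators and numerical choices behind
`sdgeno`, and what the synthetic-data generator does and does not
emulate.

## The assay model

A self-digitization (SD) chip array holds 1024 wells of 8 nL
(400 × 200 × 100 µm chambers; 16 channels × 64 wells). Loading is
passive, so the number of cells or plasmids captured per well is modeled
as Poisson with density λ (events/well). After endpoint PCR, each well
carries three fluorescence intensities: FAM (amplification probe —
positive whenever the locus amplified), HEX (mutant-allele probe) and
Cy5 (wild-type-allele probe). Analysis is endpoint-only; no
amplification-curve kinetics are modeled anywhere.

A single-cell genotype is reported only for a filled well with exactly
one imaged cell, amplification signal, and at least one allele probe
positive. All other outcomes are tracked explicitly (NonAmp, UNCALLED,
doublet-excluded, empty), because the point of the platform is that
these failure modes are observable rather than assumed away.

## Threshold calibration

Positivity thresholds are drawn per channel at `mean + k·SD` of the
negative-well intensity population, with k = 3 (FAM), 5 (Cy5), 6 (HEX).
The negative SD is measured from a density curve rather than the sample
SD so that occasional bright outliers in control arrays do not inflate
it: a Gaussian KDE (Silverman bandwidth) is evaluated on a 512-point
grid spanning the data range ± 3 bandwidths, the full width at half
maximum is read off with linear interpolation between grid points, and
SD = FWHM / 2.355. If the supra-half-maximum region is disconnected
(multimodal density) the component containing the global maximum is used
and a warning recorded. Only arrays whose template is off-target for a
probe contribute to that probe's negative distribution (NTC for FAM;
NTC + WT plasmid for HEX; NTC + MUT plasmid for Cy5); each contributing
array yields its own SD and the **maximum** across arrays is used with
the pooled negative mean — a deliberately conservative threshold. The
pooled (rather than per-array) mean is a package choice; it is the more
stable estimate and matches the threshold's definition as a shift above
the measured negative mean.

Positivity is a strict inequality (`intensity > threshold`); a tie falls
negative, conservative toward fewer false positives.

### Bleed-through correction

FAM fluorescence leaks into the HEX channel. The correction is linear:
`I_HEX,corr = I_HEX − slope · I_FAM`, with the slope taken as the mean of
per-array OLS slopes of HEX on FAM over filled, amplification-positive
wells of HEX-off-target (WT plasmid) arrays. The line is fit with a free
intercept but only the slope is applied; whether the platform's original
fit was forced through the origin is unknown, and with a free intercept
the applied correction is insensitive to a constant HEX offset. Arrays
with fewer than 10 eligible wells are skipped with a warning. Corrected
intensities may be negative and are preserved as-is (classification only
compares against a threshold).

Calibration order matters and is fixed: FAM threshold → bleed-through
fit → correction → HEX and Cy5 thresholds. The raw HEX distribution of
negative wells on amplifying control arrays is a FAM-shifted mixture
(broad and bimodal — the very artifact the correction removes), so the
HEX threshold is drawn on the corrected scale, which is also the scale
classification compares against.

## Poisson occupancy and the doublet-excess test

The loading density is estimated from the zero class only:
λ̂ = −ln(f₀) with f₀ the PCR-negative (or zero-cell) fraction of filled
wells. Expected single- and multi-event well counts follow from
P(1) = λe^(−λ) and P(>1) = 1 − P(0) − P(1). The doublet-excess test
conditions on occupancy: under Poisson loading an occupied well is
multi-event with probability P(>1)/(1 − P(0)), so the observed multi
count is tested against Binomial(n_occupied, that probability),
one-sided. Conditioning keeps the test close to nominal when λ̂ is
estimated from the same array (verified by simulation: ≤5 rejections per
100 null runs at α = 0.01).

## Allele dropout (ADO)

Heterozygous plasmids (one copy of each allele in series) are loaded at
single-copy density (λ ≈ 0.2). ADO_MUT is the rate at which these type
as wild-type; ADO_WT the rate at which they type as mutant. The
denominator is conservative: wells holding more than one plasmid are
assumed to always type heterozygous, so the Poisson-expected multi-well
count (from λ̂) is subtracted from the genotyped total:

    D = n_WT + n_HET + n_MUT − N·P(>1; λ̂),  floored at n_WT + n_MUT + 1
    ADO_MUT = n_WT / D,   ADO_WT = n_MUT / D

Subtracting the expected multis "from the heterozygous count" and "from
the genotyped total" are algebraically the same denominator, so no
switch between the two readings is needed; `correct_multi=False` instead
disables the correction entirely (used to demonstrate that at λ = 0.5
the corrected estimator is strictly less biased). Aggregates are
mean ± SD **across array replicates**, matching replicate-level error
reporting. At single-copy loading the estimator is mildly conservative
(≈0.2–0.4 percentage points low) because dropout events inside true
multi-plasmid wells are diluted while the denominator still subtracts
the full expected multi count.

## VAF and the zygosity-distribution test

VAF (%) = 100 · (N_MUT + ½·N_HET) / (N_WT + N_HET + N_MUT). A bulk VAF
near 50 % is compatible with an all-heterozygous population; the
single-cell distribution tests that directly. Under independent
per-allele dropout, an all-HET sample is expected to be called
(P_WT, P_HET, P_MUT) = (ADO_MUT, 1 − ADO_MUT − ADO_WT, ADO_WT); the
double-dropout mass (~0.5 % at the default rates) becomes UNCALLED and
is not a genotype, so it is left inside the HET complement rather than
renormalized — the approximation error is an order of magnitude below
the test's resolution. The goodness-of-fit test is a seeded Monte-Carlo
exact multinomial test (Pearson χ² statistic, 10⁵ draws, add-one
p-value; the reportable floor is 1/(draws+1) ≈ 10⁻⁵). A χ² option
(df = 2) exists for repeated calibration runs; at n ≈ 850 calls the
smallest expected class count is ≈45 and the asymptotic test's type-I
rate is within 2 points of nominal (verified over 1000 simulated null
replicates), so the two are interchangeable there.

## The synthetic-data generator

The generator is first-class, tested code: every stochastic event is
recorded in a truth table so estimators can be validated against
generative truth. Per well it draws, in fixed order for byte-identical
reproducibility at a given seed: fill failure → Poisson occupancy →
companion doublet → per-event genotype → per-copy allele dropout →
forced FP/FN → intensities → imaged cell count.

Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| wells/array | 1024 | 16 channels × 64 wells |
| λ (cells) | 0.15 | single-cell loading (~140 cells/array) |
| λ (WT/MUT plasmid controls) | 0.5 | ≈41 % occupied wells, the control-array loading density implied by the published audit counts (891 amp-positive vs 1305 all-negative wells) |
| λ (HET plasmid) | 0.2 | 6 arrays ≈ 1050–1100 genotype calls, matching the published ADO experiment (~1095 calls) |
| doublet excess | 0.10 | each occupied well recruits a companion event with this probability — the simplest mechanism for the observed super-Poisson doublet counts (cell adhesion, microstructure filtering) |
| fill failure | 0.05 | failed wells get area fraction U[0.05, 0.5) |
| ADO_WT / ADO_MUT | 0.054 / 0.085 | published per-allele dropout rates |
| bleed slope | 0.46 | published FAM→HEX correction factor |
| FP / FN rate | 0.02 / 0.08 | package choice (no numeric rates are printed for these); order of magnitude of a tuned surfactant condition |
| count error | 0.01 | residual segmentation miscounts (±1), the scale of the manual corrections the platform needed |
| zygosity mix (cells) | 0.20/0.50/0.30 | an OCI-AML3-like mixed population, VAF ≈ 55 % |

Intensities are Gaussian per channel (negatives ~N(100, 10–12);
positives N(400, 40) FAM, N(340, 55) HEX, N(290, 50) Cy5, arbitrary
units), with the bleed-through added to HEX after drawing. The Gaussian
family is an assumption — the real platform's intensity distributions
are unpublished. Both populations sit clear of the k·SD thresholds so
that false allele calls are ≪1 % and sub-threshold positives contribute
<0.5 % apparent dropout; the configured ADO probabilities are therefore
the apparent (measured) dropout rates, which is how the published rates
were defined. Consequences worth knowing: synthetic false-allele rates
are essentially zero (the real platform's 0.2–0.3 % comes from
non-Gaussian tails this model does not emulate), and the
amp-positive-but-allele-negative audit rates on plasmid controls
(≈4–7 %) are dominated by whole-well dropout rather than threshold bias.

Dropout is applied **per allele copy per event**, and a well loses an
allele only when every copy of it drops. At single-copy occupancy this
is identical to per-well dropout; at higher occupancy it is what makes
the ADO estimator's "multi-plasmid wells are always heterozygous"
assumption approximately true, and it is the regime in which the
conservative correction demonstrably reduces bias.

Rendering (off by default) draws wells as bright rectangles (aqueous
fill as the leading area fraction of the rectangle), cells as radius-4
disks, and — with a configurable merge probability — a doublet as a
single 4:1 ellipse whose isoperimetric circularity (4πA/P² ≈ 0.5 on the
pixel grid) falls below the 0.6 single-cell bound. Images are
single-channel 16-bit.

What passing tests on synthetic data do **not** show: robustness to
non-Gaussian intensity tails, spatial artifacts (flat-field, bubbles,
debris), chemistry-dependent dropout correlation between alleles, or
cell segmentation under realistic microscopy noise. The image-analysis
checks use noiseless renders; the particle-counter defaults
(min circularity 0.6, max single area ≈1.75× the single-cell area,
background = mode + 3 robust SDs from the MAD) are tool defaults, not
measured constants, and are all configurable.

## Numerical and interface choices

- Pixel rectangles are 0-based and half-open; ROIs of an array are
  pairwise disjoint by construction.
- The fill filter is inclusive (area ≥ 0.5 × max area on the array).
- Well tables are plain TSV with metadata in `#` header comments;
  floats are written at full precision (`%.17g`) and read back with
  round-trip parsing, so write→read→write is byte-stable.
- Every pipeline run writes a manifest (seed, config snapshot, package
  version); `rerun_from_manifest` reproduces the report bit-for-bit.
  Reports contain no timestamps; manifests do.
- Components are counted as at most 2 cells (the counting rule never
  assigns more per particle); any well with ≥2 total is doublet+ and
  excluded from genotyping and from FP/FN denominators.
- FPR = FP/(FP+TN) over cell-free filled wells, FNR = FN/(FN+TP) over
  single-cell wells — the standard 2×2 convention. Undefined
  denominators yield NaN, never 0.
- Single-cell UNCALLED wells count as TP for QC (amplification
  succeeded) but are excluded from genotype denominators; their rate is
  reported as the threshold-bias audit.
- Test problem sizes: distributional checks use 10⁵-well arrays;
  estimator-recovery means use 40 replicate sets of 6 arrays (Monte-
  Carlo SE ≈ 0.1 percentage points, small against the 0.5-point
  recovery criterion); the type-I calibration of the zygosity test uses
  1000 replicates at n = 847 calls.

## Known limitations

- The Gaussian intensity model understates the platform's false-allele
  and threshold-bias artifacts (see above).
- ADO is independent between alleles and between copies; correlated
  dropout (e.g. shared lysis failure) appears only as the separate
  locus-dropout (FN) channel.
- The doublet "companion" mechanism adds at most one extra event per
  well; it reproduces the qualitative super-Poisson excess, not any
  particular clustering law.
- Plasmid arrays ignore imaged cell counts entirely (plasmids are not
  imaged as particles); NTC contamination enters only through the
  false-positive rate.
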