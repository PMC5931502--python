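"""Fluorescence threshold calibration and FAM-to-HEX bleed-through correction.

Positivity thresholds are drawn at a fixed number of SDs above the mean of
the negative-well intensity population: 3 SD for the amplification probe
(FAM), 6 SD for the mutant probe (HEX) and 5 SD for the wild-type probe
(Cy5). The negative SD is measured from a kernel density curve of control
wells as FWHM/2.355, only on arrays whose template is off-target for the
probe in question, and the maximum SD across contributing arrays is used.

HEX intensities receive a spectral bleed-through correction: a best-fit
line of HEX on FAM in amplification-positive, HEX-off-target wells gives a
slope, and corrected HEX = raw HEX - slope * FAM.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import gaussian_kde, linregress

from .types import (
    ArrayData,
    BleedThroughModel,
    Channel,
    ChannelCalibration,
    TemplateKind,
    ValidationError,
    DEFAULT_K,
    HEX_CORRECTED_COLUMN,
)

#: Gaussian FWHM-to-SD conversion constant as used on-platform.
FWHM_TO_SD = 2.355

#: Which template kinds are off-target (negative) for each probe channel,
#: hence usable to characterize its negative-well distribution.
CALIBRATION_TEMPLATES = {
    Channel.FAM_amp: (TemplateKind.NTC,),
    Channel.HEX_mut: (TemplateKind.NTC, TemplateKind.WT_PLASMID),
    Channel.Cy5_wt: (TemplateKind.NTC, TemplateKind.MUT_PLASMID),
}

MIN_CALIBRATION_WELLS = 50


def select_calibration_wells(arrays: list[ArrayData], channel: Channel) -> dict[str, np.ndarray]:
    """Collect negative-well intensities for one probe channel.

    Only arrays whose template is off-target for the channel contribute
    (NTC for FAM; NTC + wild-type plasmid for the mutant probe; NTC +
    mutant plasmid for the wild-type probe), and only wells passing the
    50 %-of-max filling filter. Returns per-array intensity vectors keyed
    by array id.
    """
    from .classify import filter_filled

    channel = Channel(channel)
    eligible = CALIBRATION_TEMPLATES[channel]
    out: dict[str, np.ndarray] = {}
    for arr in arrays:
        if arr.template_kind not in eligible:
            continue
        filled, _ = filter_filled(arr.wells)
        col = channel.intensity_column
        # the mutant-probe threshold lives on the bleed-through-corrected
        # scale: calibrate it on corrected intensities when available
        if channel == Channel.HEX_mut and HEX_CORRECTED_COLUMN in filled.columns:
            col = HEX_CORRECTED_COLUMN
        out[arr.array_id] = filled[col].to_numpy(dtype=float)
    if not out:
        raise ValidationError(
            f"no eligible calibration arrays for channel {channel.value} "
            f"(need template in {[t.value for t in eligible]})"
        )
    return out


def fwhm_of_density(grid: np.ndarray, density: np.ndarray) -> float:
    """Full width at half maximum of a density curve on a grid.

    The half-max region is found around the global maximum; crossings are
    located by linear interpolation between grid points. If the
    supra-half-max region is disconnected (multimodal density), the
    component containing the global maximum is used and a warning emitted.
    """
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    if grid.shape != density.shape or grid.size < 3:
        raise ValidationError("grid and density must be equal-length vectors (>= 3 points)")
    imax = int(np.argmax(density))
    half = density[imax] / 2.0
    above = density >= half

    # detect disconnected supra-half-max regions
    n_regions = int(np.count_nonzero(np.diff(above.astype(int)) == 1) + above[0])
    if n_regions > 1:
        warnings.warn(
            "density has a disconnected half-maximum region; using the component "
            "containing the global maximum",
            stacklevel=2,
        )

    # walk left/right from the maximum to the crossings
    i = imax
    while i > 0 and above[i - 1]:
        i -= 1
    if i == 0:
        left = grid[0]
    else:
        # interpolate between grid[i-1] (below) and grid[i] (above)
        f = (half - density[i - 1]) / (density[i] - density[i - 1])
        left = grid[i - 1] + f * (grid[i] - grid[i - 1])
    j = imax
    while j < len(grid) - 1 and above[j + 1]:
        j += 1
    if j == len(grid) - 1:
        right = grid[-1]
    else:
        f = (density[j] - half) / (density[j] - density[j + 1])
        right = grid[j] + f * (grid[j + 1] - grid[j])
    return float(right - left)


def estimate_negative_sd(intensities: np.ndarray) -> tuple[float, float]:
    """Mean and FWHM-derived SD of a negative-well intensity sample.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a 512-point grid
    spanning the data range plus three bandwidths on each side; the SD is
    the density's FWHM divided by 2.355 and the mean is the sample mean.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < MIN_CALIBRATION_WELLS:
        raise ValidationError(f"need at least {MIN_CALIBRATION_WELLS} intensities, got {x.size}")
    kde = gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, 512)
    density = kde(grid)
    fwhm = fwhm_of_density(grid, density)
    return float(x.mean()), float(fwhm / FWHM_TO_SD)


def compute_threshold(
    calibration_sets: dict[str, np.ndarray], channel: Channel, k: float | None = None
) -> ChannelCalibration:
    """Combine per-array negative distributions into one channel threshold.

    Each contributing array yields its own (mean, FWHM-SD); the maximum SD
    across arrays is paired with the pooled mean of all negative wells and
    the threshold drawn at ``mean + k * sd``.
    """
    channel = Channel(channel)
    if k is None:
        k = DEFAULT_K[channel]
    if k <= 0:
        raise ValidationError("k multiplier must be positive")
    if not calibration_sets:
        raise ValidationError("at least one per-array calibration set required")
    sds = {aid: estimate_negative_sd(vals)[1] for aid, vals in calibration_sets.items()}
    max_sd = max(sds.values())
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in calibration_sets.values()])
    mean = float(pooled.mean())
    return ChannelCalibration(
        channel=channel,
        neg_mean=mean,
        neg_sd=float(max_sd),
        k=float(k),
        threshold=mean + k * max_sd,
        source_array_ids=sorted(calibration_sets),
    )


def calibrate_channel(arrays: list[ArrayData], channel: Channel, k: float | None = None) -> ChannelCalibration:
    """Select calibration wells and draw the threshold for one channel."""
    return compute_threshold(select_calibration_wells(arrays, channel), channel, k)


def calibrate_all(
    arrays: list[ArrayData], k_overrides: dict[Channel, float] | None = None
) -> tuple[dict[Channel, ChannelCalibration], BleedThroughModel]:
    """Full threshold calibration of a control-array set.

    Order matters: the FAM threshold is drawn first (NTC arrays), the
    bleed-through slope is fit in amplification-positive HEX-off-target
    wells, the correction is applied to the control arrays, and only then
    are the allele-probe thresholds drawn — the mutant-probe threshold on
    the corrected HEX scale, where its negative distribution is unimodal
    again. Returns the three channel calibrations and the fitted
    bleed-through model.
    """
    k_overrides = k_overrides or {}
    fam = calibrate_channel(arrays, Channel.FAM_amp, k_overrides.get(Channel.FAM_amp))
    bleed = fit_bleedthrough(arrays, fam)
    corrected = [apply_bleedthrough_correction(a, bleed) for a in arrays]
    cals = {
        Channel.FAM_amp: fam,
        Channel.HEX_mut: calibrate_channel(corrected, Channel.HEX_mut, k_overrides.get(Channel.HEX_mut)),
        Channel.Cy5_wt: calibrate_channel(corrected, Channel.Cy5_wt, k_overrides.get(Channel.Cy5_wt)),
    }
    return cals, bleed


def fit_bleedthrough(
    arrays: list[ArrayData],
    fam_calibration: ChannelCalibration,
    min_wells: int = 10,
) -> BleedThroughModel:
    """Fit the FAM-to-HEX bleed-through slope from HEX-off-target arrays.

    For each eligible array (template carrying no HEX-specific target but
    amplifying, i.e. wild-type plasmid), an ordinary least-squares line of
    raw HEX on FAM is fit over filled, amplification-positive wells; the
    model slope is the mean of per-array slopes. The line has a free
    intercept but only the slope enters the correction. Arrays with fewer
    than ``min_wells`` eligible wells are skipped with a warning.
    """
    from .classify import filter_filled

    slopes: list[float] = []
    for arr in arrays:
        if arr.template_kind != TemplateKind.WT_PLASMID:
            continue
        filled, _ = filter_filled(arr.wells)
        pos = filled[filled["I_FAM"] > fam_calibration.threshold]
        if len(pos) < min_wells:
            warnings.warn(
                f"array {arr.array_id}: only {len(pos)} amplification-positive wells; "
                "skipped for bleed-through fit",
                stacklevel=2,
            )
            continue
        fit = linregress(pos["I_FAM"].to_numpy(float), pos["I_HEX"].to_numpy(float))
        slopes.append(float(fit.slope))
    if not slopes:
        raise ValidationError("no eligible arrays for the bleed-through fit")
    return BleedThroughModel(slope=float(np.mean(slopes)), per_array_slopes=slopes)


def apply_bleedthrough_correction(array: ArrayData, model: BleedThroughModel) -> ArrayData:
    """Store corrected HEX = raw HEX - slope * FAM alongside the raw value.

    Corrected intensities may be negative; they are preserved as-is since
    classification only compares them to a threshold.
    """
    wells = array.wells.copy()
    wells[HEX_CORRECTED_COLUMN] = wells["I_HEX"] - model.slope * wells["I_FAM"]
    return ArrayData(
        array_id=array.array_id,
        template_kind=array.template_kind,
        wells=wells,
        metadata=dict(array.metadata),
    )


def calibration_to_dict(
    calibrations: dict[Channel, ChannelCalibration], bleed: BleedThroughModel | None = None
) -> dict:
    """JSON-serializable snapshot of a calibration run."""
    out = {
        "channels": {
            ch.value: {
                "neg_mean": cal.neg_mean,
                "neg_sd": cal.neg_sd,
                "k": cal.k,
                "threshold": cal.threshold,
                "source_array_ids": cal.source_array_ids,
            }
            for ch, cal in calibrations.items()
        }
    }
    if bleed is not None:
        out["bleedthrough"] = {
            "slope": bleed.slope,
            "per_array_slopes": bleed.per_array_slopes,
            "n_arrays": bleed.n_arrays,
        }
    return out


def calibration_from_dict(payload: dict) -> tuple[dict[Channel, ChannelCalibration], BleedThroughModel | None]:
    """Inverse of :func:`calibration_to_dict`."""
    cals = {}
    for name, d in payload["channels"].items():
        ch = Channel(name)
        cals[ch] = ChannelCalibration(
            channel=ch,
            neg_mean=d["neg_mean"],
            neg_sd=d["neg_sd"],
            k=d["k"],
            threshold=d["threshold"],
            source_array_ids=list(d.get("source_array_ids", [])),
        )
    bleed = None
    if "bleedthrough" in payload:
        b = payload["bleedthrough"]
        bleed = BleedThroughModel(slope=b["slope"], per_array_slopes=list(b.get("per_array_slopes", [])))
    return cals, bleed
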