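"""Seeded synthetic SD-chip arrays with per-well ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: Poisson cell/plasmid occupancy with an optional super-Poisson
doublet excess, Gaussian negative/positive endpoint-fluorescence
populations per channel, FAM-to-HEX spectral bleed-through, per-allele
dropout, false-positive/false-negative well events, and partial well
filling. Every stochastic event is recorded in a parallel truth table so
estimator-recovery tests can compare calls against generative truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    ArrayData,
    TemplateKind,
    ValidationError,
    N_CHANNELS,
    WELLS_PER_CHANNEL,
    WELLS_PER_ARRAY,
)

TRUTH_TABLE_COLUMNS = [
    "well_row",
    "well_col",
    "true_event_count",
    "true_genotype",
    "wt_present",
    "mut_present",
    "dropout_wt",
    "dropout_mut",
    "forced_fp",
    "forced_fn",
    "unfilled",
    "amp_signal",
    "wt_signal",
    "mut_signal",
]


@dataclass(frozen=True)
class ChannelIntensityModel:
    """Gaussian negative and positive endpoint-intensity populations."""

    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float

    def validate(self, name: str) -> None:
        vals = (self.neg_mean, self.neg_sd, self.pos_mean, self.pos_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"{name}: non-finite intensity parameter")
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ValidationError(f"{name}: intensity SDs must be positive")
        if not self.neg_mean < self.pos_mean:
            raise ValidationError(f"{name}: neg_mean must be below pos_mean")


# Defaults keep both populations clear of the 3/5/6-SD thresholds: false
# allele calls stay far below 1%, and sub-threshold positives contribute
# <0.5% apparent dropout, so the configured ADO probabilities are the
# apparent (measured) dropout rates.
DEFAULT_INTENSITY = {
    "FAM": ChannelIntensityModel(neg_mean=100.0, neg_sd=10.0, pos_mean=400.0, pos_sd=40.0),
    "HEX": ChannelIntensityModel(neg_mean=100.0, neg_sd=12.0, pos_mean=340.0, pos_sd=55.0),
    "Cy5": ChannelIntensityModel(neg_mean=100.0, neg_sd=10.0, pos_mean=290.0, pos_sd=50.0),
}


@dataclass
class SimulationConfig:
    """Parameters of one simulated array.

    Parameters
    ----------
    wells_per_array
        Number of wells (default 1024 = 16 channels x 64 wells).
    template_kind
        What the array was loaded with; controls which alleles occupied
        wells carry.
    occupancy_lambda
        Expected events (cells or plasmids) per well under Poisson loading.
        The default 0.15 corresponds to single-cell loading density
        (~140 cells per 1024-well array).
    doublet_excess
        Probability that an occupied well recruits one extra companion
        event beyond Poisson — the simplest mechanism producing the
        super-Poisson doublet excess seen on real chips (cell-cell
        adhesion, microstructure filtering).
    fill_failure_rate
        Fraction of wells that fail to digitize fully; failed wells get an
        aqueous area fraction drawn uniformly from [0.05, 0.5) and carry no
        events.
    intensity
        Per-channel Gaussian negative/positive populations (keys FAM, HEX,
        Cy5), arbitrary fluorescence units.
    bleed_slope
        FAM-to-HEX spectral bleed-through: raw HEX = base HEX +
        slope * I_FAM.
    ado_wt, ado_mut
        Per-allele-copy dropout probabilities. Applied independently to
        each allele copy of each event; a well loses an allele only when
        every copy of it drops.
    fp_rate
        Probability that an empty filled well shows amplification signal
        (pre-lysed DNA); the false positive receives a random genotype's
        allele signals.
    fn_rate
        Probability that an occupied filled well shows no amplification at
        all (locus dropout / failed lysis).
    count_error_rate
        Probability that the imaged cell count of a well is off by one
        (mimics residual segmentation errors; cells templates only).
    zygosity_mix
        (P_WT, P_HET, P_MUT) cell-genotype mix for CELLS templates.
    seed
        Seed for the generator; identical config + seed reproduces the
        array byte-for-byte.
    """

    wells_per_array: int = WELLS_PER_ARRAY
    template_kind: TemplateKind = TemplateKind.CELLS
    occupancy_lambda: float = 0.15
    doublet_excess: float = 0.10
    fill_failure_rate: float = 0.05
    intensity: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY))
    bleed_slope: float = 0.46
    ado_wt: float = 0.054
    ado_mut: float = 0.085
    fp_rate: float = 0.02
    fn_rate: float = 0.08
    count_error_rate: float = 0.01
    zygosity_mix: tuple = (0.20, 0.50, 0.30)
    seed: int = 0
    array_id: str = "sim-array"

    def __post_init__(self) -> None:
        self.template_kind = TemplateKind(self.template_kind)
        if self.wells_per_array <= 0:
            raise ValidationError("wells_per_array must be positive")
        if not (math.isfinite(self.occupancy_lambda) and self.occupancy_lambda >= 0):
            raise ValidationError("occupancy_lambda must be finite and >= 0")
        for name in (
            "doublet_excess",
            "fill_failure_rate",
            "ado_wt",
            "ado_mut",
            "fp_rate",
            "fn_rate",
            "count_error_rate",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be a probability in [0, 1]")
        if not math.isfinite(self.bleed_slope):
            raise ValidationError("bleed_slope must be finite")
        mix = tuple(float(p) for p in self.zygosity_mix)
        if len(mix) != 3 or any(p < 0 for p in mix):
            raise ValidationError("zygosity_mix must be three non-negative probabilities")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValidationError("zygosity_mix must sum to 1 within 1e-9")
        self.zygosity_mix = mix
        for key in ("FAM", "HEX", "Cy5"):
            if key not in self.intensity:
                raise ValidationError(f"missing intensity model for channel {key}")
            self.intensity[key].validate(key)


def control_config(template_kind: TemplateKind, seed: int = 0, **overrides) -> SimulationConfig:
    """Config preset for a control array of the given template kind.

    NTC arrays carry no template (lambda 0); plasmid controls are loaded at
    lambda 0.5 (~40% occupied wells, matching control-array loading
    density); cell defaults are unchanged. Plasmids are not imaged as
    particles, so cell-count error channels are switched off.
    """
    kind = TemplateKind(template_kind)
    base = dict(template_kind=kind, seed=seed, array_id=f"{kind.value.lower()}-{seed}")
    if kind == TemplateKind.NTC:
        base.update(occupancy_lambda=0.0, fp_rate=0.0, fn_rate=0.0, doublet_excess=0.0)
    elif kind in (TemplateKind.WT_PLASMID, TemplateKind.MUT_PLASMID):
        base.update(occupancy_lambda=0.5, fp_rate=0.0, fn_rate=0.0, doublet_excess=0.0)
    elif kind == TemplateKind.HET_PLASMID:
        # single-copy loading for allele-dropout estimation
        base.update(occupancy_lambda=0.2, fp_rate=0.0, fn_rate=0.0, doublet_excess=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


def _allele_unit_counts(cfg: SimulationConfig, counts: np.ndarray, rng: np.random.Generator):
    """Number of WT / MUT allele copies carried by each well's events."""
    kind = cfg.template_kind
    if kind == TemplateKind.WT_PLASMID:
        return counts.copy(), np.zeros_like(counts)
    if kind == TemplateKind.MUT_PLASMID:
        return np.zeros_like(counts), counts.copy()
    if kind == TemplateKind.HET_PLASMID:
        # each plasmid carries one copy of each allele in series
        return counts.copy(), counts.copy()
    if kind == TemplateKind.NTC:
        return np.zeros_like(counts), np.zeros_like(counts)
    # CELLS: each cell draws a genotype from the mix
    split = rng.multinomial(counts, cfg.zygosity_mix)
    n_wt_cells, n_het_cells, n_mut_cells = split[:, 0], split[:, 1], split[:, 2]
    return n_wt_cells + n_het_cells, n_mut_cells + n_het_cells


def simulate_array(config: SimulationConfig) -> tuple[ArrayData, pd.DataFrame]:
    """Simulate one array, returning the well table and its truth table.

    The draw order is fixed so that identical configs (including seed)
    produce byte-identical tables.
    """
    cfg = config
    n = cfg.wells_per_array
    rng = np.random.default_rng(cfg.seed)

    # well addressing: row-major over (channel, well) positions
    rows = np.arange(n) // WELLS_PER_CHANNEL
    cols = np.arange(n) % WELLS_PER_CHANNEL

    # 1. filling
    unfilled = rng.random(n) < cfg.fill_failure_rate
    partial_area = rng.uniform(0.05, 0.5, n)
    area_fraction = np.where(unfilled, partial_area, 1.0)

    # 2. occupancy: Poisson plus companion doublet excess; unfilled wells
    #    never capture events
    counts = rng.poisson(cfg.occupancy_lambda, n)
    companion = (counts > 0) & (rng.random(n) < cfg.doublet_excess)
    counts = counts + companion.astype(counts.dtype)
    counts[unfilled] = 0

    # 3. allele content and per-copy dropout
    wt_units, mut_units = _allele_unit_counts(cfg, counts, rng)
    wt_surviving = rng.binomial(wt_units, 1.0 - cfg.ado_wt)
    mut_surviving = rng.binomial(mut_units, 1.0 - cfg.ado_mut)
    wt_present = wt_units > 0
    mut_present = mut_units > 0
    dropout_wt = wt_present & (wt_surviving == 0)
    dropout_mut = mut_present & (mut_surviving == 0)

    # 4. forced well-level errors
    occupied = counts > 0
    filled = ~unfilled
    forced_fn = occupied & filled & (rng.random(n) < cfg.fn_rate)
    forced_fp = (~occupied) & filled & (rng.random(n) < cfg.fp_rate)
    # a false positive shows a random genotype's allele signals
    if cfg.template_kind == TemplateKind.CELLS:
        fp_geno = rng.choice(3, size=n, p=cfg.zygosity_mix)
    elif cfg.template_kind == TemplateKind.WT_PLASMID:
        fp_geno = np.zeros(n, dtype=int)
    elif cfg.template_kind == TemplateKind.MUT_PLASMID:
        fp_geno = np.full(n, 2)
    else:  # NTC / HET plasmid contamination assumed heterozygous
        fp_geno = np.ones(n, dtype=int)
    fp_has_wt = fp_geno != 2
    fp_has_mut = fp_geno != 0

    # 5. realized probe signals
    amp_signal = (occupied & ~forced_fn) | forced_fp
    wt_signal = (occupied & ~forced_fn & (wt_surviving > 0)) | (forced_fp & fp_has_wt)
    mut_signal = (occupied & ~forced_fn & (mut_surviving > 0)) | (forced_fp & fp_has_mut)

    # 6. endpoint intensities: Gaussian population per signal status, then
    #    FAM bleeds into HEX
    def draw(model: ChannelIntensityModel, positive: np.ndarray) -> np.ndarray:
        neg = rng.normal(model.neg_mean, model.neg_sd, n)
        pos = rng.normal(model.pos_mean, model.pos_sd, n)
        return np.where(positive, pos, neg)

    i_fam = draw(cfg.intensity["FAM"], amp_signal)
    hex_base = draw(cfg.intensity["HEX"], mut_signal)
    i_cy5 = draw(cfg.intensity["Cy5"], wt_signal)
    i_hex = hex_base + cfg.bleed_slope * i_fam

    # 7. imaged cell counts (cells templates only; plasmids are invisible)
    if cfg.template_kind == TemplateKind.CELLS:
        cell_count = counts.copy()
        miscount = rng.random(n) < cfg.count_error_rate
        direction = np.where(rng.random(n) < 0.5, -1, 1)
        cell_count = np.maximum(cell_count + miscount * direction, 0)
    else:
        cell_count = np.zeros(n, dtype=int)

    wells = pd.DataFrame(
        {
            "array_id": cfg.array_id,
            "well_row": rows,
            "well_col": cols,
            "area_fraction": area_fraction,
            "cell_count": cell_count.astype(int),
            "I_FAM": i_fam,
            "I_HEX": i_hex,
            "I_Cy5": i_cy5,
        }
    )

    genotype = np.where(
        wt_present & mut_present, "HET", np.where(wt_present, "WT", np.where(mut_present, "MUT", "NONE"))
    )
    truth = pd.DataFrame(
        {
            "well_row": rows,
            "well_col": cols,
            "true_event_count": counts.astype(int),
            "true_genotype": genotype,
            "wt_present": wt_present,
            "mut_present": mut_present,
            "dropout_wt": dropout_wt,
            "dropout_mut": dropout_mut,
            "forced_fp": forced_fp,
            "forced_fn": forced_fn,
            "unfilled": unfilled,
            "amp_signal": amp_signal,
            "wt_signal": wt_signal,
            "mut_signal": mut_signal,
        }
    )

    array = ArrayData(
        array_id=cfg.array_id,
        template_kind=cfg.template_kind,
        wells=wells,
        metadata={"seed": cfg.seed, "occupancy_lambda": cfg.occupancy_lambda},
    )
    return array, truth


def simulate_control_bundle(seed: int = 0, n_ntc: int = 2, n_wt: int = 2, n_mut: int = 2, **overrides):
    """Simulate the control arrays a calibration run needs (NTC/WT/MUT)."""
    arrays, truths = [], []
    idx = 0
    for kind, count in (
        (TemplateKind.NTC, n_ntc),
        (TemplateKind.WT_PLASMID, n_wt),
        (TemplateKind.MUT_PLASMID, n_mut),
    ):
        for i in range(count):
            cfg = control_config(kind, seed=seed + idx, **overrides)
            cfg = replace(cfg, array_id=f"{kind.value.lower()}-{i}")
            arr, tru = simulate_array(cfg)
            arrays.append(arr)
            truths.append(tru)
            idx += 1
    return arrays, truths


# ---------------------------------------------------------------------------
# optional raster rendering of a cell-imaging frame


@dataclass(frozen=True)
class GridGeometry:
    """Pixel layout of the rectangular well grid in a rendered image."""

    n_rows: int = N_CHANNELS
    n_cols: int = WELLS_PER_CHANNEL
    well_width: int = 40  # pixels, along the column axis
    well_height: int = 20
    x_pitch: int = 48
    y_pitch: int = 28
    x_margin: int = 8
    y_margin: int = 8

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("grid must have positive dimensions")
        if self.x_pitch < self.well_width or self.y_pitch < self.well_height:
            raise ValidationError("well pitch smaller than well size: wells would overlap")

    @property
    def image_shape(self) -> tuple[int, int]:
        h = 2 * self.y_margin + (self.n_rows - 1) * self.y_pitch + self.well_height
        w = 2 * self.x_margin + (self.n_cols - 1) * self.x_pitch + self.well_width
        return (h, w)

    def well_rect(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(x0, y0, width, height), half-open pixel coordinates."""
        x0 = self.x_margin + col * self.x_pitch
        y0 = self.y_margin + row * self.y_pitch
        return (x0, y0, self.well_width, self.well_height)


@dataclass(frozen=True)
class RenderParams:
    """Appearance of the rendered cell-imaging frame (16-bit grayscale)."""

    background_level: float = 500.0
    background_noise_sd: float = 0.0
    well_level: float = 2000.0  # aqueous region above background
    cell_level: float = 20000.0  # stained nuclei are bright
    cell_radius: int = 4  # pixels
    merge_probability: float = 0.0  # doublets rendered as one elongated blob

    def __post_init__(self) -> None:
        if self.cell_radius < 1:
            raise ValidationError("cell_radius must be >= 1 pixel")
        if not 0.0 <= self.merge_probability <= 1.0:
            raise ValidationError("merge_probability must be in [0, 1]")


def render_array_image(
    array: ArrayData,
    truth: pd.DataFrame,
    geometry: GridGeometry,
    seed: int = 0,
    params: RenderParams = RenderParams(),
) -> tuple[np.ndarray, list]:
    """Render a pre-PCR cell-imaging frame of the array.

    Wells are drawn as bright rectangles at grid positions (the aqueous
    fill), each true cell as a bright disk, and — with probability
    ``params.merge_probability`` — a doublet as a single elongated blob
    whose circularity falls below the single-cell bound. Returns the
    16-bit image and the list of :class:`~sdgeno.imaging.WellROI` used, so
    segmentation tests have ground-truth ROIs.
    """
    from skimage.draw import disk, ellipse

    from .imaging import WellROI

    n_wells = len(array.wells)
    if n_wells > geometry.n_rows * geometry.n_cols:
        raise ValidationError("geometry grid too small for the array")

    rng = np.random.default_rng(seed)
    shape = geometry.image_shape
    img = np.full(shape, params.background_level, dtype=float)
    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, shape)

    rois = []
    counts = truth["true_event_count"].to_numpy()
    for i in range(n_wells):
        row = int(array.wells["well_row"].iloc[i])
        col = int(array.wells["well_col"].iloc[i])
        x0, y0, w, h = geometry.well_rect(row, col)
        rois.append(
            WellROI(array_id=array.array_id, channel_index=row, well_index=col, x0=x0, y0=y0, width=w, height=h)
        )
        area_frac = float(array.wells["area_fraction"].iloc[i])
        # aqueous fill occupies the leading fraction of the well rectangle
        fill_w = max(int(round(w * area_frac)), 1)
        img[y0 : y0 + h, x0 : x0 + fill_w] += params.well_level

        c = int(counts[i])
        if c == 0:
            continue
        r = params.cell_radius
        merged = c == 2 and rng.random() < params.merge_probability
        if merged:
            # one elongated blob (aspect ~4): non-circular, counted as 2
            cy, cx = y0 + h // 2, x0 + w // 2
            rr, cc = ellipse(cy, cx, r, min(4 * r, w // 2 - 1), shape=shape)
            img[rr, cc] = params.cell_level
        else:
            # place cells on a horizontal line, separated by >2r
            spacing = max(2 * r + 3, (w - 2 * r - 2) // max(c, 1))
            for j in range(c):
                cx = x0 + r + 1 + j * spacing
                cx = min(cx, x0 + w - r - 2)
                cy = y0 + h // 2
                rr, cc = disk((cy, cx), r, shape=shape)
                img[rr, cc] = params.cell_level

    img = np.clip(img, 0, 65535).astype(np.uint16)
    return img, rois
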