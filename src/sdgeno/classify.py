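"""Well filtering, PCR-positivity calls, zygosity calls and QC categories.

A single-cell genotype is only reported for a filled well in which exactly
one cell was imaged, the amplification probe is positive, and at least one
allele-specific probe is positive. Wells with two or more cells are
excluded (doublet+); amplification-positive wells with both allele probes
negative are UNCALLED. For cell arrays, the cross of imaged cell count and
amplification outcome yields the TP/FP/FN/TN QC categories; a false
negative is equivalent to a locus dropout in this single-locus assay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    ArrayData,
    ARRAY_MAP_CODES,
    Channel,
    ChannelCalibration,
    HEX_CORRECTED_COLUMN,
    QCCategory,
    TemplateKind,
    ValidationError,
    Zygosity,
    N_CHANNELS,
    WELLS_PER_CHANNEL,
)

#: A well is "filled" if its aqueous area is at least half the maximum
#: aqueous area observed on the array.
FILL_FRACTION_OF_MAX = 0.5


def filter_filled(wells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a well table into filled and excluded wells.

    Filled means area_fraction >= 0.5 x the maximum area fraction on the
    array (inclusive boundary). Raises if the array shows no aqueous area
    at all (failed load).
    """
    if "area_fraction" not in wells.columns:
        raise ValidationError("well table lacks area_fraction")
    max_area = wells["area_fraction"].max()
    if not max_area > 0:
        raise ValidationError("all aqueous areas are zero: array failed to load")
    mask = wells["area_fraction"] >= FILL_FRACTION_OF_MAX * max_area
    return wells[mask], wells[~mask]


def call_pcr_status(
    wells: pd.DataFrame, calibrations: dict[Channel, ChannelCalibration]
) -> pd.DataFrame:
    """Per-channel positivity: intensity strictly above threshold.

    HEX is compared using the bleed-through-corrected intensity, which must
    already be present. Ties at the threshold fall negative (conservative
    toward fewer false positives).
    """
    for ch in Channel:
        if ch not in calibrations:
            raise ValidationError(f"missing calibration for channel {ch.value}")
    if HEX_CORRECTED_COLUMN not in wells.columns:
        raise ValidationError("bleed-through correction has not been applied (no I_HEX_corr)")
    return pd.DataFrame(
        {
            "amp_pos": wells["I_FAM"] > calibrations[Channel.FAM_amp].threshold,
            "wt_pos": wells["I_Cy5"] > calibrations[Channel.Cy5_wt].threshold,
            "mut_pos": wells[HEX_CORRECTED_COLUMN] > calibrations[Channel.HEX_mut].threshold,
        },
        index=wells.index,
    )


def _probe_zygosity(amp: np.ndarray, wt: np.ndarray, mut: np.ndarray) -> np.ndarray:
    """Zygosity from probe booleans for wells already amp-evaluated."""
    out = np.where(
        amp,
        np.where(
            wt & mut,
            Zygosity.HET.value,
            np.where(wt, Zygosity.WT.value, np.where(mut, Zygosity.MUT.value, Zygosity.UNCALLED.value)),
        ),
        Zygosity.NON_AMP.value,
    )
    return out


def call_zygosity(
    wells: pd.DataFrame, pcr_status: pd.DataFrame, template_kind: TemplateKind
) -> pd.Series:
    """Assign a zygosity call to every filled well.

    Cell arrays: wells with >= 2 imaged cells are DOUBLET_EXCLUDED; a
    single-cell well is genotyped from its probe pattern (NON_AMP if the
    amplification probe is negative); a zero-cell well gets no genotype
    (NO_CELL — QC accounts for it as FP or TN). Plasmid and NTC arrays
    apply the probe logic to every filled well, ignoring cell counts.
    """
    if (wells["cell_count"] < 0).any():
        raise ValidationError("negative cell count")
    amp = pcr_status["amp_pos"].to_numpy(bool)
    wt = pcr_status["wt_pos"].to_numpy(bool)
    mut = pcr_status["mut_pos"].to_numpy(bool)
    probe_call = _probe_zygosity(amp, wt, mut)
    if TemplateKind(template_kind) == TemplateKind.CELLS:
        count = wells["cell_count"].to_numpy(int)
        out = np.where(
            count >= 2,
            Zygosity.DOUBLET_EXCLUDED.value,
            np.where(count == 1, probe_call, Zygosity.NO_CELL.value),
        )
    else:
        out = probe_call
    return pd.Series(out, index=wells.index, name="zygosity")


def categorize_qc(wells: pd.DataFrame, pcr_status: pd.DataFrame) -> pd.Series:
    """QC category of each filled well of a cell array.

    Doublet+ wells form their own category; otherwise the 2x2 of imaged
    cell presence x amplification outcome gives TP/FP/FN/TN.
    """
    count = wells["cell_count"].to_numpy(int)
    if (count < 0).any():
        raise ValidationError("negative cell count")
    amp = pcr_status["amp_pos"].to_numpy(bool)
    out = np.where(
        count >= 2,
        QCCategory.DOUBLET_PLUS.value,
        np.where(
            count == 1,
            np.where(amp, QCCategory.TP.value, QCCategory.FN.value),
            np.where(amp, QCCategory.FP.value, QCCategory.TN.value),
        ),
    )
    return pd.Series(out, index=wells.index, name="qc_category")


def classify_array(
    array: ArrayData, calibrations: dict[Channel, ChannelCalibration]
) -> pd.DataFrame:
    """Full per-well call table for one (bleed-through-corrected) array.

    Returns the well table extended with ``filled``, the three positivity
    booleans, ``zygosity`` and — for cell arrays — ``qc_category``.
    Excluded (unfilled) wells are labeled EMPTY and carry no PCR calls.
    """
    filled, excluded = filter_filled(array.wells)
    status = call_pcr_status(filled, calibrations)
    zyg = call_zygosity(filled, status, array.template_kind)

    table = array.wells.copy()
    table["filled"] = False
    table.loc[filled.index, "filled"] = True
    for col in ("amp_pos", "wt_pos", "mut_pos"):
        table[col] = pd.array([pd.NA] * len(table), dtype="boolean")
        table.loc[filled.index, col] = status[col].to_numpy()
    table["zygosity"] = Zygosity.EMPTY.value
    table.loc[filled.index, "zygosity"] = zyg
    if array.template_kind == TemplateKind.CELLS:
        qc = categorize_qc(filled, status)
        table["qc_category"] = pd.NA
        table.loc[filled.index, "qc_category"] = qc
    return table


def genotype_counts(call_table: pd.DataFrame) -> dict[str, int]:
    """Counts of WT/HET/MUT/UNCALLED calls on an array."""
    z = call_table["zygosity"]
    return {
        "n_wt": int((z == Zygosity.WT.value).sum()),
        "n_het": int((z == Zygosity.HET.value).sum()),
        "n_mut": int((z == Zygosity.MUT.value).sum()),
        "n_uncalled": int((z == Zygosity.UNCALLED.value).sum()),
    }


def qc_counts(call_table: pd.DataFrame) -> dict[str, int]:
    """Counts of QC categories over the filled wells of a cell array."""
    if "qc_category" not in call_table.columns:
        raise ValidationError("call table has no qc_category (not a cell array?)")
    q = call_table.loc[call_table["filled"], "qc_category"]
    return {cat.value: int((q == cat.value).sum()) for cat in QCCategory}


def occupancy_counts(call_table: pd.DataFrame) -> dict[str, int]:
    """Filled-well occupancy histogram (0 / 1 / >1 imaged cells)."""
    c = call_table.loc[call_table["filled"], "cell_count"]
    return {
        "n_zero": int((c == 0).sum()),
        "n_single": int((c == 1).sum()),
        "n_multi": int((c >= 2).sum()),
    }


def amp_negative_fraction(call_table: pd.DataFrame) -> float:
    """Fraction of filled wells with no amplification signal.

    This is the PCR-negative fraction that the Poisson occupancy model
    inverts to estimate the loading density lambda.
    """
    amp = call_table.loc[call_table["filled"], "amp_pos"]
    if len(amp) == 0:
        raise ValidationError("no filled wells")
    return float((~amp.astype(bool)).sum() / len(amp))


def array_map_text(call_table: pd.DataFrame) -> str:
    """Render the 16 x 64 array as single-character zygosity codes.

    Codes: E empty, N non-amp, W wild-type, H heterozygous, M mutant,
    U uncalled, D doublet-excluded, '.' filled cell-array well without a
    cell.
    """
    grid = np.full((N_CHANNELS, WELLS_PER_CHANNEL), "?", dtype="<U1")
    code_by_name = {z.value: c for z, c in ARRAY_MAP_CODES.items()}
    for _, row in call_table.iterrows():
        r, c = int(row["well_row"]), int(row["well_col"])
        if 0 <= r < N_CHANNELS and 0 <= c < WELLS_PER_CHANNEL:
            grid[r, c] = code_by_name.get(row["zygosity"], "?")
    return "\n".join("".join(line) for line in grid)
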