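"""Core domain types shared across the SD-chip genotyping pipeline.

A self-digitization (SD) chip partitions a cell or plasmid suspension into
1024 stationary 8 nL wells (16 parallel channels, each addressing 64 wells).
After endpoint PCR, each well carries fluorescence in three channels:
FAM (locus amplification probe), HEX (mutant-allele probe) and Cy5
(wild-type-allele probe). Well tables are held as pandas DataFrames with one
row per well; these enums and dataclasses give the vocabulary the rest of
the package shares.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

N_CHANNELS = 16
WELLS_PER_CHANNEL = 64
WELLS_PER_ARRAY = N_CHANNELS * WELLS_PER_CHANNEL

#: Column order of a well table (one row per well).
WELL_TABLE_COLUMNS = [
    "array_id",
    "well_row",
    "well_col",
    "area_fraction",
    "cell_count",
    "I_FAM",
    "I_HEX",
    "I_Cy5",
]

#: Column added by the bleed-through correction step.
HEX_CORRECTED_COLUMN = "I_HEX_corr"


class TemplateKind(str, enum.Enum):
    """What was loaded into an array: controls, plasmid standards, or cells."""

    NTC = "NTC"  # no template control
    WT_PLASMID = "WT_PLASMID"
    MUT_PLASMID = "MUT_PLASMID"
    HET_PLASMID = "HET_PLASMID"  # one WT + one MUT amplicon copy per plasmid
    CELLS = "CELLS"


class Channel(str, enum.Enum):
    """Fluorescence channels, named probe-first as they are used downstream."""

    FAM_amp = "FAM_amp"
    HEX_mut = "HEX_mut"
    Cy5_wt = "Cy5_wt"

    @property
    def intensity_column(self) -> str:
        return {
            Channel.FAM_amp: "I_FAM",
            Channel.HEX_mut: "I_HEX",
            Channel.Cy5_wt: "I_Cy5",
        }[self]


#: Default SD-multiplier per probe channel: 3 for the amplification probe,
#: 6 for the mutant probe, 5 for the wild-type probe.
DEFAULT_K = {Channel.FAM_amp: 3.0, Channel.HEX_mut: 6.0, Channel.Cy5_wt: 5.0}


class Zygosity(str, enum.Enum):
    """Per-well genotype call for a filled well (EMPTY marks unfilled)."""

    EMPTY = "EMPTY"  # well failed the aqueous-area fill filter
    NON_AMP = "NON_AMP"  # single cell but no amplification-probe signal
    WT = "WT"
    HET = "HET"
    MUT = "MUT"
    UNCALLED = "UNCALLED"  # amp-positive but both allele probes negative
    DOUBLET_EXCLUDED = "DOUBLET_EXCLUDED"  # >=2 cells; excluded from genotyping
    NO_CELL = "NO_CELL"  # filled cell-array well with zero cells


class QCCategory(str, enum.Enum):
    """Per-well QC class for cell arrays, from cell imaging x PCR outcome."""

    TP = "TP"  # one cell, amplification positive
    FP = "FP"  # no cell, amplification positive
    FN = "FN"  # one cell, amplification negative (locus dropout)
    TN = "TN"  # no cell, amplification negative
    DOUBLET_PLUS = "DOUBLET_PLUS"  # two or more cells


#: Single-character codes for the text array map (Fig-style layout).
ARRAY_MAP_CODES = {
    Zygosity.EMPTY: "E",
    Zygosity.NON_AMP: "N",
    Zygosity.WT: "W",
    Zygosity.HET: "H",
    Zygosity.MUT: "M",
    Zygosity.UNCALLED: "U",
    Zygosity.DOUBLET_EXCLUDED: "D",
    Zygosity.NO_CELL: ".",
}


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class ArrayData:
    """One SD-chip array: a well table plus template metadata.

    ``wells`` has one row per well with columns :data:`WELL_TABLE_COLUMNS`
    (plus ``I_HEX_corr`` once the bleed-through correction has run).
    """

    array_id: str
    template_kind: TemplateKind
    wells: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in WELL_TABLE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValidationError(f"well table missing columns: {missing}")
        self.template_kind = TemplateKind(self.template_kind)

    @property
    def n_wells(self) -> int:
        return len(self.wells)


@dataclass
class ChannelCalibration:
    """Positivity threshold for one probe channel.

    ``threshold = neg_mean + k * neg_sd`` where ``neg_sd`` is the maximum
    FWHM-derived SD across contributing control arrays and ``neg_mean`` the
    pooled mean of their negative wells.
    """

    channel: Channel
    neg_mean: float
    neg_sd: float
    k: float
    threshold: float
    source_array_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError("k multiplier must be positive")
        if not self.threshold > self.neg_mean:
            raise ValidationError("threshold must exceed the negative mean")


@dataclass
class BleedThroughModel:
    """FAM-to-HEX spectral bleed-through: corrected = I_HEX - slope * I_FAM."""

    slope: float
    per_array_slopes: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.slope):
            raise ValidationError("bleed-through slope must be finite")

    @property
    def n_arrays(self) -> int:
        return len(self.per_array_slopes)
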