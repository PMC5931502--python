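"""Physical SD-chip geometry.

Each array has 16 parallel channels addressing 64 wells each (1024 wells).
A well is a rectangular chamber of 400 x 200 x 100 um, i.e. 8 nL.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import ValidationError

# 1 nL = 1e6 um^3
_UM3_PER_NL = 1.0e6


@dataclass(frozen=True)
class WellDimensions:
    """Well chamber dimensions in micrometres."""

    length_um: float = 400.0
    width_um: float = 200.0
    depth_um: float = 100.0

    def __post_init__(self) -> None:
        if min(self.length_um, self.width_um, self.depth_um) <= 0:
            raise ValidationError("well dimensions must be positive")

    @property
    def volume_nl(self) -> float:
        """Well capacity in nanolitres."""
        return self.length_um * self.width_um * self.depth_um / _UM3_PER_NL


#: The fabricated well: 400 x 200 x 100 um -> 8 nL.
STANDARD_WELL = WellDimensions()


def well_volume_nl(dims: WellDimensions = STANDARD_WELL) -> float:
    """Volume of one digitized well in nL (8 nL for the standard chip)."""
    return dims.volume_nl
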