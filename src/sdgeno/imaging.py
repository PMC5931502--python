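"""Per-well measurements from array raster images.

Three quantities per well drive the downstream pipeline: the aqueous area
fraction (wells under half-full are excluded), the adjusted integrated
density (AID — integrated fluorescence normalized to well area), and the
cell count from the pre-PCR nuclear-stain image. Cell counting follows the
particle rule used on real chips: connected bright components are filtered
by size, and a component that is large or non-circular is counted as two
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .types import ValidationError, N_CHANNELS, WELLS_PER_CHANNEL


@dataclass(frozen=True)
class WellROI:
    """Pixel rectangle of one well; half-open, 0-based coordinates."""

    array_id: str
    channel_index: int  # 0..15
    well_index: int  # 0..63
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("ROI must have positive extent")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width))

    @property
    def area_px(self) -> int:
        return self.width * self.height

    def within(self, image_shape: tuple[int, int]) -> bool:
        return (
            self.x0 >= 0
            and self.y0 >= 0
            and self.x0 + self.width <= image_shape[1]
            and self.y0 + self.height <= image_shape[0]
        )


@dataclass(frozen=True)
class CellDetectionParams:
    """Size and shape criteria of the particle counter.

    The underlying rule is qualitative — large and non-circular particles
    count as two cells — so the cutoffs here are tool defaults, not
    measured constants: circularity (4*pi*A/P^2) below 0.6, or area above
    ``max_single_area`` (set it to ~1.75x the median single-cell area),
    marks a merged doublet.
    """

    background_threshold: float | None = None  # None -> robust estimate
    min_area: int = 9  # pixels; smaller components are debris
    max_single_area: int = 88  # ~1.75x area of a radius-4 disk
    min_circularity: float = 0.6

    def __post_init__(self) -> None:
        if not self.min_area < self.max_single_area:
            raise ValidationError("min_area must be below max_single_area")
        if not 0.0 < self.min_circularity <= 1.0:
            raise ValidationError("min_circularity must be in (0, 1]")


def build_well_grid(geometry, image_shape: tuple[int, int] | None = None, array_id: str = "array") -> list[WellROI]:
    """Lay out the disjoint well ROIs of a grid geometry.

    With the standard geometry this returns 1024 ROIs in row-major
    (channel, well) order. If ``image_shape`` is given, the grid must fit.
    """
    required = geometry.image_shape
    if image_shape is not None and (required[0] > image_shape[0] or required[1] > image_shape[1]):
        raise ValidationError(f"grid requires image of at least {required}, got {image_shape}")
    rois = []
    for row in range(geometry.n_rows):
        for col in range(geometry.n_cols):
            x0, y0, w, h = geometry.well_rect(row, col)
            rois.append(
                WellROI(array_id=array_id, channel_index=row, well_index=col, x0=x0, y0=y0, width=w, height=h)
            )
    return rois


def _check_roi(image: np.ndarray, roi: WellROI) -> None:
    if not roi.within(image.shape):
        raise ValidationError(f"ROI {roi} exceeds image bounds {image.shape}")


def robust_background_threshold(image: np.ndarray, n_sigma: float = 3.0) -> float:
    """Background cutoff: modal intensity plus ``n_sigma`` robust SDs.

    The mode is taken from the integer-rounded intensity histogram and the
    SD from the median absolute deviation (x1.4826), so sparse bright
    cells do not move the estimate.
    """
    flat = np.asarray(image, dtype=float).ravel()
    ints = np.round(flat).astype(np.int64)
    ints -= ints.min()
    mode = float(np.bincount(ints).argmax() + np.round(flat).min())
    mad = float(np.median(np.abs(flat - np.median(flat))))
    robust_sd = 1.4826 * mad
    return mode + n_sigma * robust_sd


def measure_aqueous_area(image: np.ndarray, roi: WellROI, background_threshold: float) -> float:
    """Fraction of ROI pixels whose intensity exceeds the background."""
    _check_roi(image, roi)
    patch = image[roi.slices]
    if patch.size == 0:
        raise ValidationError("empty ROI")
    return float(np.count_nonzero(patch > background_threshold) / patch.size)


def compute_aid(image: np.ndarray, roi: WellROI) -> float:
    """Adjusted integrated density: summed intensity / ROI pixel area."""
    _check_roi(image, roi)
    patch = image[roi.slices]
    return float(patch.sum(dtype=np.float64) / patch.size)


def component_circularity(area: float, perimeter: float) -> float:
    """Isoperimetric circularity 4*pi*A/P^2 (1 for a perfect disk)."""
    if perimeter <= 0:
        return 1.0
    return float(4.0 * np.pi * area / perimeter**2)


def count_cells(image: np.ndarray, roi: WellROI, params: CellDetectionParams) -> int:
    """Count stained cells inside one well ROI.

    Pixels above the background threshold are segmented into connected
    components; components below ``min_area`` are discarded; a component
    that is large (area > max_single_area) or non-circular (circularity <
    min_circularity) is counted as two cells, any other as one.
    """
    _check_roi(image, roi)
    patch = np.asarray(image[roi.slices], dtype=float)
    thr = params.background_threshold
    if thr is None:
        thr = robust_background_threshold(image)
    mask = patch > thr
    if not mask.any():
        return 0
    labels = label(mask, connectivity=2)
    total = 0
    for prop in regionprops(labels):
        if prop.area < params.min_area:
            continue
        circ = component_circularity(prop.area, prop.perimeter)
        doublet = prop.area > params.max_single_area or circ < params.min_circularity
        total += 2 if doublet else 1
    return total


def extract_well_table(
    cell_image: np.ndarray,
    rois: list[WellROI],
    params: CellDetectionParams = CellDetectionParams(),
    intensity_images: dict[str, np.ndarray] | None = None,
    area_image: np.ndarray | None = None,
    background_threshold: float | None = None,
) -> pd.DataFrame:
    """Measure every well of an array into the standard well-table schema.

    ``cell_image`` is the pre-PCR nuclear-stain frame used for counting;
    ``intensity_images`` optionally maps channel names (FAM/HEX/Cy5) to
    post-PCR frames for AID; ``area_image`` (default: the cell image) is
    thresholded for the aqueous area fraction. Well tables produced here
    are interchangeable with simulated ones.
    """
    if not rois:
        raise ValidationError("no ROIs supplied")
    if background_threshold is None:
        # the frame has up to three intensity classes (dry background,
        # aqueous fill, stained cells); the lowest multi-Otsu cut separates
        # background from aqueous. Fall back to plain Otsu when fewer
        # classes are present.
        from skimage.filters import threshold_multiotsu, threshold_otsu

        src = np.asarray(cell_image if area_image is None else area_image)
        try:
            background_threshold = float(threshold_multiotsu(src, classes=3)[0])
        except ValueError:
            background_threshold = float(threshold_otsu(src))
    area_src = cell_image if area_image is None else area_image
    cell_params = params
    if cell_params.background_threshold is None:
        cell_params = CellDetectionParams(
            background_threshold=robust_background_threshold(cell_image),
            min_area=params.min_area,
            max_single_area=params.max_single_area,
            min_circularity=params.min_circularity,
        )

    records = []
    for roi in rois:
        rec = {
            "array_id": roi.array_id,
            "well_row": roi.channel_index,
            "well_col": roi.well_index,
            "area_fraction": measure_aqueous_area(area_src, roi, background_threshold),
            "cell_count": count_cells(cell_image, roi, cell_params),
        }
        for ch, col in (("FAM", "I_FAM"), ("HEX", "I_HEX"), ("Cy5", "I_Cy5")):
            img = (intensity_images or {}).get(ch)
            rec[col] = compute_aid(img, roi) if img is not None else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)
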