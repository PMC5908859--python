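"""Per-cell readout of the unmodified raw channels.

After detection, each cell's pixel coordinates are read back from the
*unmodified* rasters — never from the contrast-enhanced image used only to
find the cells.  Summing raw intensities over a cell's pixels gives its
chlorophyll and lipid amount (arbitrary fluorescence units); dividing by the
pixel count gives the corresponding density, interpretable as intracellular
concentration.  Pixels at or above the camera's saturation ceiling are
counted per cell so downstream analyses can flag or filter clipped cells
instead of silently biasing amounts.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .errors import ReadoutError
from .image_io import CELL_TABLE_COLUMNS, FluorescenceField
from .segmentation import LabelMask, SegmentationParams, to_grayscale

__all__ = ["CellRecord", "readout_channel", "measure_cells", "records_to_frame"]


@dataclasses.dataclass
class CellRecord:
    """Measured properties of one detected cell."""

    field_id: str
    cell_id: int
    pixel_count: int
    equiv_diameter: float
    chl_amount: float
    lipid_amount: float
    chl_density: float
    lipid_density: float
    saturated_fraction_chl: float
    saturated_fraction_lipid: float
    timepoint: float = 0.0
    condition: str = ""


def equivalent_diameter(pixel_count: int | float) -> float:
    """Diameter of the circle with the same pixel area: ``2*sqrt(A/pi)``."""
    return 2.0 * math.sqrt(pixel_count / math.pi)


def readout_channel(
    mask: LabelMask, raw: np.ndarray, ceiling: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (summed intensity, saturated fraction) from one raw channel.

    ``raw`` must be the unmodified 2-D raster.  For each label k the summed
    intensity over its pixels and the fraction of those pixels at or above
    ``ceiling`` are returned (arrays of length ``n_cells``, index 0 = cell 1).
    """
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape != mask.labels.shape:
        raise ReadoutError(
            f"raw raster shape {raw.shape} incompatible with mask {mask.labels.shape}"
        )
    n = mask.n_cells
    if n == 0:
        return np.zeros(0), np.zeros(0)
    flat_labels = mask.labels.ravel()
    flat_vals = raw.ravel().astype(np.float64)
    sums = np.bincount(flat_labels, weights=flat_vals, minlength=n + 1)[1:]
    counts = np.bincount(flat_labels, minlength=n + 1)[1:]
    saturated = np.bincount(
        flat_labels, weights=(flat_vals >= ceiling).astype(np.float64), minlength=n + 1
    )[1:]
    return sums, saturated / counts


def measure_cells(
    mask: LabelMask,
    field: FluorescenceField,
    params: SegmentationParams | None = None,
) -> list[CellRecord]:
    """One :class:`CellRecord` per label, read from the unmodified channels.

    RGB channels are collapsed with the same grayscale mode used for
    segmentation but are *not* contrast-enhanced; densities are amount per
    pixel of cell area.
    """
    params = params or SegmentationParams()
    mode = params.grayscale_mode if field.is_rgb else "single-channel"
    chl_gray = to_grayscale(field.chl_raw, mode)
    lipid_gray = to_grayscale(field.lipid_raw, mode)
    ceiling = float(field.saturation_ceiling)
    chl_sums, chl_sat = readout_channel(mask, chl_gray, ceiling)
    lipid_sums, lipid_sat = readout_channel(mask, lipid_gray, ceiling)
    counts = mask.pixel_counts()
    records = []
    for k in range(mask.n_cells):
        n_px = int(counts[k])
        records.append(
            CellRecord(
                field_id=field.field_id,
                cell_id=k + 1,
                pixel_count=n_px,
                equiv_diameter=equivalent_diameter(n_px),
                chl_amount=float(chl_sums[k]),
                lipid_amount=float(lipid_sums[k]),
                chl_density=float(chl_sums[k]) / n_px,
                lipid_density=float(lipid_sums[k]) / n_px,
                saturated_fraction_chl=float(chl_sat[k]),
                saturated_fraction_lipid=float(lipid_sat[k]),
                timepoint=field.timepoint,
                condition=field.condition,
            )
        )
    return records


def records_to_frame(records: list[CellRecord] | pd.DataFrame) -> pd.DataFrame:
    """Cell records as a DataFrame in canonical column order."""
    if isinstance(records, pd.DataFrame):
        return records.loc[:, CELL_TABLE_COLUMNS].copy()
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=CELL_TABLE_COLUMNS
    )
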