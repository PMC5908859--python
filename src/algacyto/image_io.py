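"""Reading and writing of dual-channel fluorescence fields and per-cell tables.

A *field* is one microscope field of view acquired twice through different
filter cubes: once for chlorophyll autofluorescence (the trigger channel used
to detect cells) and once for Nile-Red fluorescence (neutral lipids).  The two
rasters are pixel-aligned by construction of epi-fluorescence filter-cube
switching, so no registration is performed.

Intensities are never rescaled on input: quantification downstream must see
the camera counts exactly as stored.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelPairingError, FormatError

__all__ = [
    "FluorescenceField",
    "read_field",
    "write_field",
    "pair_fields",
    "write_cell_table",
    "read_cell_table",
    "write_manifest",
    "CELL_TABLE_COLUMNS",
]

_DTYPE_BITS = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}

#: Column order of the per-cell CSV table.
CELL_TABLE_COLUMNS = [
    "field_id",
    "cell_id",
    "pixel_count",
    "equiv_diameter",
    "chl_amount",
    "lipid_amount",
    "chl_density",
    "lipid_density",
    "saturated_fraction_chl",
    "saturated_fraction_lipid",
    "timepoint",
    "condition",
]


@dataclasses.dataclass
class FluorescenceField:
    """One field of view: raw chlorophyll + Nile-Red rasters and metadata.

    Parameters
    ----------
    field_id:
        Identifier of the field (typically the shared filename stem).
    chl_raw, lipid_raw:
        Unmodified intensity rasters, ``(H, W)`` grayscale or ``(H, W, 3)``
        RGB, in camera counts (arbitrary fluorescence units).
    bit_depth:
        8 or 16.  Used to derive the dynamic-range maximum.
    saturation_ceiling:
        Intensity at or above which a pixel counts as clipped by the camera.
    timepoint:
        Sampling time in days.
    condition:
        Culture label, e.g. ``"control"`` or ``"minusN"``.
    """

    field_id: str
    chl_raw: np.ndarray
    lipid_raw: np.ndarray
    bit_depth: int = 8
    saturation_ceiling: float | None = None
    timepoint: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.chl_raw = np.asarray(self.chl_raw)
        self.lipid_raw = np.asarray(self.lipid_raw)
        if self.chl_raw.shape != self.lipid_raw.shape:
            raise ChannelPairingError(
                f"channel shapes differ: chlorophyll {self.chl_raw.shape} "
                f"vs lipid {self.lipid_raw.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.saturation_ceiling is None:
            self.saturation_ceiling = float(self.dynamic_range_max)
        if self.saturation_ceiling > self.dynamic_range_max:
            raise FormatError(
                "saturation_ceiling exceeds the dynamic-range maximum "
                f"({self.saturation_ceiling} > {self.dynamic_range_max})"
            )
        for name, arr in (("chl_raw", self.chl_raw), ("lipid_raw", self.lipid_raw)):
            if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[-1] != 3):
                raise FormatError(f"{name} must be 2-D or (H, W, 3), got {arr.shape}")
            if arr.size and (arr.min() < 0 or arr.max() > self.dynamic_range_max):
                raise FormatError(
                    f"{name} intensities outside [0, {self.dynamic_range_max}]"
                )

    @property
    def dynamic_range_max(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def is_rgb(self) -> bool:
        """True when the channels still need grayscale conversion downstream."""
        return self.chl_raw.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.chl_raw.shape[:2]


def _load_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop an alpha plane (PNG)
        arr = arr[..., :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[-1] != 3):
        raise FormatError(f"{path}: expected 2-D grayscale or RGB, got shape {arr.shape}")
    if arr.dtype not in _DTYPE_BITS:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype} (need uint8/uint16)")
    return arr


def read_field(
    chl_path: str | Path,
    lipid_path: str | Path,
    *,
    field_id: str | None = None,
    bit_depth: int | None = None,
    saturation_ceiling: float | None = None,
    timepoint: float = 0.0,
    condition: str = "",
) -> FluorescenceField:
    """Read one chlorophyll/Nile-Red image pair into a validated field.

    Bit depth is inferred from the file dtype (uint8 -> 8, uint16 -> 16)
    unless overridden, which matters for cameras that store 12-bit data in
    16-bit containers.  Intensities are returned exactly as stored.
    """
    chl = _load_raster(chl_path)
    lipid = _load_raster(lipid_path)
    if chl.shape != lipid.shape:
        raise ChannelPairingError(
            f"{chl_path} and {lipid_path} have different shapes: "
            f"{chl.shape} vs {lipid.shape}"
        )
    if chl.dtype != lipid.dtype:
        raise ChannelPairingError(
            f"{chl_path} and {lipid_path} have different dtypes: "
            f"{chl.dtype} vs {lipid.dtype}"
        )
    inferred = _DTYPE_BITS[chl.dtype]
    return FluorescenceField(
        field_id=field_id or Path(chl_path).stem,
        chl_raw=chl,
        lipid_raw=lipid,
        bit_depth=bit_depth or inferred,
        saturation_ceiling=saturation_ceiling,
        timepoint=timepoint,
        condition=condition,
    )


def write_field(field: FluorescenceField, chl_path: str | Path, lipid_path: str | Path) -> None:
    """Write both channels of a field as TIFF (or PNG, by extension)."""
    dtype = np.uint8 if field.bit_depth == 8 else np.uint16
    for arr, path in ((field.chl_raw, chl_path), (field.lipid_raw, lipid_path)):
        out = np.asarray(arr).astype(dtype)
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, out)
        else:
            iio.imwrite(path, out)


def pair_fields(
    directory: str | Path,
    chl_suffix: str = "_chl",
    lipid_suffix: str = "_nr",
) -> list[tuple[str, Path, Path]]:
    """Pair channel files in a directory by filename suffix.

    ``<stem><chl_suffix>.<ext>`` pairs with ``<stem><lipid_suffix>.<ext>``;
    the shared ``<stem>`` becomes the field id.  Returns pairs sorted by id.
    """
    directory = Path(directory)
    chl_files: dict[str, Path] = {}
    lipid_files: dict[str, Path] = {}
    for path in sorted(directory.iterdir()):
        if not path.is_file() or path.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        stem = path.stem
        if stem.endswith(chl_suffix):
            chl_files[stem[: -len(chl_suffix)]] = path
        elif stem.endswith(lipid_suffix):
            lipid_files[stem[: -len(lipid_suffix)]] = path
    pairs = []
    for fid, chl_path in sorted(chl_files.items()):
        if fid not in lipid_files:
            raise ChannelPairingError(f"no lipid channel for field {fid!r}")
        pairs.append((fid, chl_path, lipid_files[fid]))
    orphans = sorted(set(lipid_files) - set(chl_files))
    if orphans:
        raise ChannelPairingError(f"lipid channels without chlorophyll partner: {orphans}")
    return pairs


def write_cell_table(records: Iterable | pd.DataFrame, path: str | Path) -> None:
    """Write per-cell records to CSV (one row per cell; lossless round trip).

    Floats are serialized with 17 significant digits, so reading the file
    back reproduces every numeric value bit-exactly.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.loc[:, CELL_TABLE_COLUMNS]
    else:
        frame = pd.DataFrame(
            [dataclasses.asdict(r) for r in records], columns=CELL_TABLE_COLUMNS
        )
    frame.to_csv(path, index=False, float_format="%.17g")


_CELL_TABLE_DTYPES = {
    "cell_id": np.int64,
    "pixel_count": np.int64,
    "equiv_diameter": np.float64,
    "chl_amount": np.float64,
    "lipid_amount": np.float64,
    "chl_density": np.float64,
    "lipid_density": np.float64,
    "saturated_fraction_chl": np.float64,
    "saturated_fraction_lipid": np.float64,
    "timepoint": np.float64,
}


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell CSV written by :func:`write_cell_table`."""
    frame = pd.read_csv(
        path, dtype={"field_id": str, "condition": str}, float_precision="round_trip"
    )
    missing = [c for c in CELL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing cell-table columns {missing}")
    frame["condition"] = frame["condition"].fillna("")
    return frame.astype(_CELL_TABLE_DTYPES)


def write_manifest(path: str | Path, manifest: dict) -> None:
    """Write the JSON run manifest (config echo, version, per-field counts)."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
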