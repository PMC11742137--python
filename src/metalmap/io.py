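"""Reading, consolidating and persisting elemental-map channels.

Elemental imaging instruments (LA-ICP-MS, XRF) and their processing
software (e.g. iolite) export one rectangular intensity grid per element,
typically as a CSV or Excel sheet.  This module reads those per-element
grids, stacks them into a single multichannel :class:`ElementalMap`, and
round-trips the map through a chunked zarr store so downstream stages can
work from one consolidated file.

Coordinate convention used throughout the package: rasters are row-major,
``(x, y) = (col, row)``, origin at the top-left, pixel centers at integer
pixel coordinates, physical position ``x_um = x_px * pixel_size_um``.
Missing data (unablated rows, detector dropouts) are first-class: values
are NaN internally and a parallel boolean mask is authoritative.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelGrid",
    "ElementalMap",
    "WSIRaster",
    "ChannelParseError",
    "StoreError",
    "read_channel_table",
    "consolidate_channels",
    "write_store",
    "read_store",
    "read_wsi_raster",
]


class ChannelParseError(ValueError):
    """Raised when a per-element grid file cannot be parsed."""


class StoreError(ValueError):
    """Raised when a consolidated store is absent or its metadata corrupt."""


@dataclass
class ChannelGrid:
    """A single-element intensity grid as exported by acquisition software.

    Values are non-negative intensities (counts or µg/g — units are opaque
    metadata); missing cells are NaN.
    """

    element_name: str
    values: np.ndarray  # 2-D float array, NaN = missing
    source_path: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError(
                f"channel grid {self.element_name!r} must be a non-empty 2-D array"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class ElementalMap:
    """Multichannel elemental image with physical pixel size and missing mask.

    ``data`` is indexed ``(channel, row, col)``; ``missing_mask`` has the
    same shape and is authoritative — wherever it is True the value is
    ignored by every statistic in the package.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    missing_mask: np.ndarray | None = None
    frame_id: str = "elemental"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ElementalMap.data must be 3-D (channel, row, col)")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.data)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.data.shape:
                raise ValueError("missing_mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel with missing entries set to NaN."""
        idx = self.channel_index(name)
        out = self.data[idx].copy()
        out[self.missing_mask[idx]] = np.nan
        return out

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None


@dataclass
class WSIRaster:
    """An exported whole-slide image level as an 8-bit RGB array."""

    pixels: np.ndarray  # (row, col, 3) uint8
    pixel_size_um: float
    frame_id: str = "wsi"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("WSIRaster.pixels must be (row, col, 3)")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


def _cell_to_float(cell, path: str, row: int, col: int) -> float:
    if cell is None:
        return np.nan
    if isinstance(cell, str):
        cell = cell.strip()
        if cell == "" or cell.lower() in {"nan", "na"}:
            return np.nan
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ChannelParseError(
            f"{path}: cell at row {row}, column {col} ({cell!r}) is not numeric"
        ) from None


def _rows_to_grid(rows: list[list], path: str, has_header: bool) -> np.ndarray:
    if has_header and rows:
        rows = [r[1:] for r in rows[1:]]
    rows = [r for r in rows if len(r) > 0]
    if not rows:
        raise ChannelParseError(f"{path}: no numeric cells found")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ChannelParseError(
                f"{path}: ragged row {i + 1}: {len(r)} cells, expected {width}"
            )
    grid = np.array(
        [
            [_cell_to_float(c, path, i, j) for j, c in enumerate(r)]
            for i, r in enumerate(rows)
        ],
        dtype=float,
    )
    if grid.size == 0 or np.all(np.isnan(grid)):
        raise ChannelParseError(f"{path}: no numeric cells found")
    return grid


def read_channel_table(
    path: str | Path,
    dialect: str = "csv",
    has_header: bool = False,
    element_name: str | None = None,
    sheet: str | None = None,
) -> ChannelGrid:
    """Read a single-element grid from a CSV file or Excel sheet.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"csv"`` or ``"excel"``.
    has_header
        If True the first row (column headers) and first column (row
        index) are stripped before parsing — iolite-style exports
        sometimes carry coordinate headers.
    element_name
        Override the element name; defaults to the Excel sheet name or
        the file stem.
    sheet
        Excel sheet to read (default: first sheet).

    Empty cells become NaN missing markers, never zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        with open(path, newline="") as fh:
            rows = [row for row in csv.reader(fh)]
        name = element_name or path.stem
    elif dialect == "excel":
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb[sheet] if sheet is not None else wb.worksheets[0]
        rows = [list(r) for r in ws.iter_rows(values_only=True)]
        # read_only worksheets may pad TRAILING all-None rows; interior
        # blank rows are real missing data and must survive
        while rows and all(c is None for c in rows[-1]):
            rows.pop()
        default = ws.title if ws.title != "Sheet" else path.stem
        name = element_name or default
        wb.close()
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'excel'")
    grid = _rows_to_grid(rows, str(path), has_header)
    if np.nanmin(grid) < 0:
        raise ChannelParseError(f"{path}: negative intensities present")
    return ChannelGrid(element_name=name, values=grid, source_path=str(path))


def consolidate_channels(
    grids: Sequence[ChannelGrid],
    pixel_size_um: float,
    frame_id: str = "elemental",
) -> ElementalMap:
    """Stack per-element grids into one multichannel :class:`ElementalMap`.

    Grids must share an identical shape and carry unique element names;
    channel order follows input order and missing markers propagate into
    the map's missing mask.
    """
    if len(grids) == 0:
        raise ValueError("need at least one channel grid")
    shape0 = grids[0].shape
    for g in grids[1:]:
        if g.shape != shape0:
            raise ValueError(
                f"channel {g.element_name!r} has shape {g.shape}, "
                f"but {grids[0].element_name!r} has shape {shape0}"
            )
    names = [g.element_name for g in grids]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate element names: {dupes}")
    data = np.stack([g.values for g in grids], axis=0)
    return ElementalMap(
        data=data,
        channel_names=names,
        pixel_size_um=pixel_size_um,
        missing_mask=np.isnan(data),
        frame_id=frame_id,
    )


_FORMAT_NAME = "metalmap-store"
_FORMAT_VERSION = 1
_CHUNKS = (1, 512, 512)


def write_store(emap: ElementalMap, path: str | Path) -> None:
    """Persist a map as a chunked zarr group (single scale).

    Layout: array ``data`` chunked ``(1, 512, 512)``, boolean array
    ``missing_mask``, and group attributes ``channel_names``,
    ``pixel_size_um``, ``frame_id``.  Optional companion arrays
    (``tissue_mask``, ``region_labels``) are written by other modules
    into the same group.
    """
    import zarr

    root = zarr.open_group(str(path), mode="w")
    chunks = tuple(min(c, s) for c, s in zip(_CHUNKS, emap.data.shape))
    arr = root.create_array(
        "data", shape=emap.data.shape, dtype="float64", chunks=chunks
    )
    arr[:] = emap.data
    mask = root.create_array(
        "missing_mask", shape=emap.data.shape, dtype="bool", chunks=chunks
    )
    mask[:] = emap.missing_mask
    root.attrs.update(
        {
            "format": _FORMAT_NAME,
            "format_version": _FORMAT_VERSION,
            "channel_names": list(emap.channel_names),
            "pixel_size_um": float(emap.pixel_size_um),
            "frame_id": emap.frame_id,
        }
    )
    # human-readable sidecar for tools that do not speak zarr
    sidecar = Path(path) / "metadata.json"
    sidecar.write_text(
        json.dumps(
            {
                "channel_names": list(emap.channel_names),
                "pixel_size_um": float(emap.pixel_size_um),
                "frame_id": emap.frame_id,
                "shape": list(emap.data.shape),
            },
            indent=2,
        )
    )


def read_store(path: str | Path) -> ElementalMap:
    """Load a map written by :func:`write_store` (bit-exact round trip)."""
    import zarr

    path = Path(path)
    if not path.exists():
        raise StoreError(f"store not found: {path}")
    try:
        root = zarr.open_group(str(path), mode="r")
    except Exception as exc:  # zarr raises various errors for non-stores
        raise StoreError(f"cannot open store {path}: {exc}") from exc
    attrs = dict(root.attrs)
    for key in ("channel_names", "pixel_size_um", "frame_id"):
        if key not in attrs:
            raise StoreError(f"store {path} missing required attribute {key!r}")
    if "data" not in root:
        raise StoreError(f"store {path} has no 'data' array")
    data = np.asarray(root["data"])
    if "missing_mask" in root:
        mask = np.asarray(root["missing_mask"]).astype(bool)
    else:
        mask = np.isnan(data)
    return ElementalMap(
        data=data,
        channel_names=list(attrs["channel_names"]),
        pixel_size_um=float(attrs["pixel_size_um"]),
        missing_mask=mask,
        frame_id=str(attrs["frame_id"]),
    )


def _tiff_pixel_size(path: Path) -> float | None:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        tags = page.tags
        if "XResolution" not in tags:
            return None
        num, den = tags["XResolution"].value
        if num == 0:
            return None
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
        unit = int(unit)
        per_unit = num / den  # pixels per unit
        if unit == 3:  # centimeter
            um_per_unit = 1e4
        elif unit == 2:  # inch
            um_per_unit = 25400.0
        else:  # RESUNIT.NONE — treat as pixels per µm
            um_per_unit = 1.0
        return um_per_unit / per_unit


def read_wsi_raster(
    path: str | Path, pixel_size_um: float | None = None, frame_id: str = "wsi"
) -> WSIRaster:
    """Read an exported TIFF/PNG raster level of a whole-slide image.

    Grayscale inputs are replicated to 3 channels; an alpha channel is
    dropped.  The physical pixel size comes from the caller, else from
    the TIFF resolution tag; if neither is available an error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        px = tifffile.imread(str(path))
        if pixel_size_um is None:
            pixel_size_um = _tiff_pixel_size(path)
    else:
        from PIL import Image

        with Image.open(path) as im:
            px = np.asarray(im)
    if pixel_size_um is None:
        raise ValueError(
            f"{path}: no resolution metadata found and pixel_size_um not given"
        )
    px = np.asarray(px)
    if px.dtype != np.uint8:
        px = np.clip(px, 0, 255).astype(np.uint8)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    elif px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    elif px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"{path}: unsupported image shape {px.shape}")
    return WSIRaster(pixels=px, pixel_size_um=float(pixel_size_um), frame_id=frame_id)
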