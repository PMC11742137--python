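"""Pathology annotation ingest, transform, rasterization and export.

Pathologists outline tissue structures (Tumor, Stroma, Duct, ...) on the
H&E whole-slide image in QuPath or ASAP; those polygons are parsed here,
pushed through the estimated planar transform into the elemental-map
frame, and rasterized into an integer label map so per-region statistics
can index elemental pixels directly.

Conventions: annotation vertices are held in physical µm; GeoJSON and
ASAP files store WSI pixel coordinates, converted on ingest via the WSI
pixel size.  Rasterization assigns each pixel the id of the LAST
annotation (input order) whose filled polygon — even-odd rule, holes
excluded — strictly contains the pixel center; uncovered pixels are 0.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

from .register import PlanarTransform, apply_to_points

__all__ = [
    "Annotation",
    "AnnotationSet",
    "RegionLabelMap",
    "parse_geojson",
    "parse_asap_xml",
    "transform_annotations",
    "rasterize",
    "write_geojson",
    "polygon_area",
]


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (n, 2) vertices."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Annotation:
    """One labelled region polygon (exterior ring plus optional holes), µm."""

    label: str
    exterior: np.ndarray  # (n, 2)
    holes: list[np.ndarray] = field(default_factory=list)
    frame_id: str = "wsi"

    def __post_init__(self) -> None:
        self.exterior = _as_ring(self.exterior)
        self.holes = [_as_ring(h) for h in self.holes]
        if abs(polygon_area(self.exterior)) <= 0:
            raise ValueError(f"annotation {self.label!r} has zero area")

    @property
    def area(self) -> float:
        """Unsigned area (exterior minus holes), µm²."""
        a = abs(polygon_area(self.exterior))
        return a - sum(abs(polygon_area(h)) for h in self.holes)

    def to_shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.exterior, holes=[h for h in self.holes])


def _as_ring(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("polygon ring must be an (n, 2) array")
    # drop an explicit closing vertex; rings are implicitly closed
    if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(np.unique(v, axis=0)) < 3:
        raise ValueError("polygon ring needs >= 3 distinct vertices")
    return v


@dataclass
class AnnotationSet:
    """Ordered annotations in one frame plus a stable label -> id table."""

    annotations: list[Annotation]
    frame_id: str = "wsi"
    label_table: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for a in self.annotations:
            if a.frame_id != self.frame_id:
                raise ValueError(
                    f"annotation {a.label!r} is in frame {a.frame_id!r}, "
                    f"set is {self.frame_id!r}"
                )
        if self.label_table is None:
            table: dict[str, int] = {}
            for a in self.annotations:
                if a.label not in table:
                    table[a.label] = len(table) + 1
            self.label_table = table
        else:
            ids = sorted(self.label_table.values())
            if ids != list(range(1, len(ids) + 1)):
                raise ValueError("label ids must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.annotations)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.annotations]


@dataclass
class RegionLabelMap:
    """Integer raster of region ids (0 = background) on the elemental grid."""

    labels: np.ndarray
    label_table: dict[int, str]
    pixel_size_um: float
    frame_id: str = "elemental"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.label_table = {int(k): str(v) for k, v in self.label_table.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise ValueError(f"label map contains ids not in label_table: {unknown}")

    def region_mask(self, label: str) -> np.ndarray:
        ids = [k for k, v in self.label_table.items() if v == label]
        if not ids:
            raise KeyError(f"unknown region label {label!r}")
        return np.isin(self.labels, ids)


def parse_geojson(path: str | Path, pixel_size_um: float) -> AnnotationSet:
    """Parse a QuPath-dialect GeoJSON FeatureCollection of polygons.

    Coordinates are WSI pixels at base resolution, converted to µm via
    ``pixel_size_um``.  Labels come from ``classification.name``, then
    ``name``, else ``"unclassified"``.  MultiPolygons split into one
    annotation per part; non-polygon geometries are skipped with a
    warning.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed GeoJSON: {exc}") from exc
    if doc.get("type") == "FeatureCollection":
        features = doc.get("features", [])
    elif doc.get("type") == "Feature":
        features = [doc]
    else:
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    annotations: list[Annotation] = []
    skipped = 0
    for feat in features:
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        cls = props.get("classification") or {}
        label = cls.get("name") or props.get("name") or "unclassified"
        gtype = geom.get("type")
        if gtype == "Polygon":
            polys = [geom["coordinates"]]
        elif gtype == "MultiPolygon":
            polys = list(geom["coordinates"])
        else:
            skipped += 1
            continue
        for rings in polys:
            ext = np.asarray(rings[0], dtype=float) * pixel_size_um
            holes = [np.asarray(r, dtype=float) * pixel_size_um for r in rings[1:]]
            annotations.append(
                Annotation(label=label, exterior=ext, holes=holes, frame_id="wsi")
            )
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} non-polygon feature(s)", stacklevel=2
        )
    return AnnotationSet(annotations=annotations, frame_id="wsi")


def parse_asap_xml(path: str | Path, pixel_size_um: float) -> AnnotationSet:
    """Parse an ASAP ``<ASAP_Annotations>`` document of Polygon annotations.

    Labels come from the PartOfGroup attribute (falling back to Name);
    vertices are ordered by their Order attribute regardless of document
    order.  Non-polygon annotation types are skipped with a warning.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "ASAP_Annotations":
        raise ValueError(f"{path}: not an ASAP_Annotations document")
    annotations: list[Annotation] = []
    skipped = 0
    for ann in root.iter("Annotation"):
        if ann.get("Type", "Polygon") != "Polygon":
            skipped += 1
            continue
        group = ann.get("PartOfGroup") or ""
        label = group if group and group != "None" else (ann.get("Name") or "unclassified")
        coords = []
        for c in ann.iter("Coordinate"):
            coords.append(
                (int(c.get("Order", 0)), float(c.get("X")), float(c.get("Y")))
            )
        if not coords:
            continue
        coords.sort(key=lambda t: t[0])
        verts = np.array([(x, y) for _, x, y in coords], dtype=float) * pixel_size_um
        annotations.append(Annotation(label=label, exterior=verts, frame_id="wsi"))
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} non-polygon annotation(s)", stacklevel=2
        )
    return AnnotationSet(annotations=annotations, frame_id="wsi")


def transform_annotations(
    aset: AnnotationSet, T: PlanarTransform
) -> AnnotationSet:
    """Map every vertex through ``T``; labels kept, frame id updated."""
    if aset.frame_id != T.source_frame_id:
        raise ValueError(
            f"annotation frame {aset.frame_id!r} does not match transform "
            f"source {T.source_frame_id!r}"
        )
    out = [
        Annotation(
            label=a.label,
            exterior=apply_to_points(T, a.exterior),
            holes=[apply_to_points(T, h) for h in a.holes],
            frame_id=T.target_frame_id,
        )
        for a in aset.annotations
    ]
    return AnnotationSet(
        annotations=out,
        frame_id=T.target_frame_id,
        label_table=dict(aset.label_table),
    )


def rasterize(
    aset: AnnotationSet,
    shape: tuple[int, int],
    pixel_size_um: float,
    frame_id: str | None = None,
) -> RegionLabelMap:
    """Burn annotations into an integer label raster on a target grid.

    A pixel takes the id of the last annotation (input order) whose
    polygon strictly contains the pixel center; holes are excluded and
    uncovered pixels stay 0.
    """
    if frame_id is not None and aset.frame_id != frame_id:
        raise ValueError(
            f"annotation frame {aset.frame_id!r} does not match raster "
            f"frame {frame_id!r}"
        )
    rows, cols = shape
    labels = np.zeros((rows, cols), dtype=np.int32)
    ps = float(pixel_size_um)
    for a in aset.annotations:
        rid = aset.label_table[a.label]
        poly = a.to_shapely()
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.ceil(minx / ps - 0.5)), 0)
        c1 = min(int(np.floor(maxx / ps + 0.5)), cols - 1)
        r0 = max(int(np.ceil(miny / ps - 0.5)), 0)
        r1 = min(int(np.floor(maxy / ps + 0.5)), rows - 1)
        if c1 < c0 or r1 < r0:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        inside = shapely.contains_xy(poly, cc.ravel() * ps, rr.ravel() * ps)
        sub = labels[r0 : r1 + 1, c0 : c1 + 1]
        sub[inside.reshape(sub.shape)] = rid
    table = {v: k for k, v in aset.label_table.items()}
    return RegionLabelMap(
        labels=labels,
        label_table=table,
        pixel_size_um=ps,
        frame_id=aset.frame_id,
    )


def write_geojson(
    aset: AnnotationSet, path: str | Path, pixel_size_um: float
) -> None:
    """Write a QuPath-compatible FeatureCollection (pixel coordinates).

    Vertices convert back from µm to WSI pixels; each feature carries
    ``classification.name``.  Rings are explicitly closed as GeoJSON
    requires.
    """

    def _ring(v: np.ndarray) -> list[list[float]]:
        px = np.asarray(v, dtype=float) / pixel_size_um
        closed = np.vstack([px, px[:1]])
        return [[float(x), float(y)] for x, y in closed]

    features = []
    for a in aset.annotations:
        rings = [_ring(a.exterior)] + [_ring(h) for h in a.holes]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": rings},
                "properties": {
                    "objectType": "annotation",
                    "classification": {"name": a.label},
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, ensure_ascii=False))
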