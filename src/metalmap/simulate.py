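"""Synthetic paired fixtures: elemental map + WSI + annotations + landmarks.

Patient imaging data cannot ship with the package, so every pipeline
stage is exercised against generated fixtures with known ground truth.
A fixture emulates one serial-section pair: a disc of tissue on an
elemental map (5 µm/px by default) whose annotated regions draw their
per-element abundances from known hurdle-gamma laws, and an H&E-style
RGB rendering of the *same* geometry on a 0.25 µm/px whole-slide raster
related to the map by a known similarity transform (rotation ≤ 15°,
scale 0.95–1.05, translation of a few hundred µm — plausible
serial-section mounting offsets).  Landmarks are true correspondences
plus optional Gaussian jitter; whole scan rows can be marked missing to
emulate incomplete ablation.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import Annotation, AnnotationSet, RegionLabelMap, rasterize, transform_annotations
from .io import ChannelGrid, ElementalMap, WSIRaster, consolidate_channels
from .register import LandmarkPairs, PlanarTransform, apply_to_points, invert

__all__ = [
    "HurdleLaw",
    "RegionSpec",
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "make_channel_files",
    "write_fixture_dir",
    "default_regions",
]

#: Region vocabulary used by the default fixtures (breast-tissue style).
REGION_VOCABULARY = [
    "Duct", "Fat", "Immune Cells", "Interface", "Lobule",
    "Normal Fibrous Stroma", "Stroma", "Tumor",
]

#: Default panel: P31 is the matrix element (phospholipids make it high and
#: near-ubiquitous across tissue), the trace metals vary by region.
DEFAULT_ELEMENTS = ["P31", "Fe57", "Zn66", "Cu63"]


@dataclass(frozen=True)
class HurdleLaw:
    """Per-pixel abundance law: zero with prob ``p_zero``, else gamma."""

    p_zero: float
    gamma_shape: float
    gamma_mean: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        zero = rng.random(n) < self.p_zero
        vals = rng.gamma(self.gamma_shape, self.gamma_mean / self.gamma_shape, n)
        vals[zero] = 0.0
        return vals


@dataclass
class RegionSpec:
    """One annotated region: a polygon (elemental-frame µm) + element laws."""

    label: str
    exterior: np.ndarray  # (n, 2) µm in the elemental frame
    laws: dict[str, HurdleLaw]

    def __post_init__(self) -> None:
        self.exterior = np.asarray(self.exterior, dtype=float)


def _square(cx: float, cy: float, half: float) -> np.ndarray:
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


def default_regions(center: tuple[float, float] = (400.0, 400.0)) -> list[RegionSpec]:
    """Four disjoint square regions inside the default tissue disc.

    225 µm sides (45×45 = 2025 pixels at 5 µm/px) give every region
    enough pixels for stable hurdle-gamma estimation.  Laws differ by
    region and element so group contrasts have real signal.  The
    half-size keeps square edges strictly between elemental pixel
    centers: an edge exactly on a line of pixel centers would make
    whole rows of the rasterization knife-edge.
    """
    cx, cy = center
    off, half = 120.0, 112.5
    law = HurdleLaw
    return [
        RegionSpec("Tumor", _square(cx - off, cy - off, half), {
            "P31": law(0.02, 3.0, 25.0),
            "Fe57": law(0.10, 2.0, 6.0),
            "Zn66": law(0.20, 2.0, 8.0),
            "Cu63": law(0.30, 1.5, 3.0),
        }),
        RegionSpec("Stroma", _square(cx + off, cy - off, half), {
            "P31": law(0.02, 3.0, 18.0),
            "Fe57": law(0.20, 2.0, 3.0),
            "Zn66": law(0.30, 2.0, 4.0),
            "Cu63": law(0.50, 1.5, 1.5),
        }),
        RegionSpec("Duct", _square(cx - off, cy + off, half), {
            "P31": law(0.02, 3.0, 22.0),
            "Fe57": law(0.15, 3.0, 5.0),
            "Zn66": law(0.25, 2.5, 6.0),
            "Cu63": law(0.40, 1.5, 2.0),
        }),
        RegionSpec("Fat", _square(cx + off, cy + off, half), {
            "P31": law(0.05, 2.0, 12.0),
            "Fe57": law(0.50, 1.5, 1.0),
            "Zn66": law(0.50, 1.5, 2.0),
            "Cu63": law(0.60, 1.0, 1.0),
        }),
    ]


@dataclass
class FixtureSpec:
    """Full recipe for one synthetic serial-section pair."""

    seed: int = 0
    wsi_pixel_size_um: float = 0.25
    elem_pixel_size_um: float = 5.0
    elem_shape: tuple[int, int] = (160, 160)  # 800×800 µm at 5 µm/px
    tissue_center_um: tuple[float, float] = (400.0, 400.0)
    tissue_radius_um: float = 345.0
    elements: list[str] = field(default_factory=lambda: list(DEFAULT_ELEMENTS))
    regions: list[RegionSpec] | None = None  # None = default_regions()
    #: abundance in tissue outside any annotated region, per element;
    #: elements not listed fall back to the modest trace law
    tissue_laws: dict[str, HurdleLaw] = field(
        default_factory=lambda: {"P31": HurdleLaw(0.03, 2.5, 15.0)}
    )
    tissue_fallback_law: HurdleLaw = HurdleLaw(0.5, 1.0, 0.8)
    background_law: HurdleLaw = HurdleLaw(0.9, 1.0, 0.05)
    true_transform: PlanarTransform | None = None  # None = sample similarity
    landmark_n: int = 8
    landmark_noise_um: float = 0.0
    missing_rows: list[int] = field(default_factory=list)


@dataclass
class Fixture:
    """Generated fixture with full ground truth."""

    wsi: WSIRaster
    emap: ElementalMap
    annotations: AnnotationSet  # WSI frame (as a pathologist would supply)
    landmarks: LandmarkPairs
    true_transform: PlanarTransform  # elemental -> wsi, physical µm
    truth_labels: RegionLabelMap  # elemental frame, ground-truth rasterization
    tissue_truth: np.ndarray  # boolean disc mask on the elemental grid
    spec: FixtureSpec


def _sample_similarity(
    rng: np.random.Generator, center: tuple[float, float]
) -> PlanarTransform:
    """Rotation ≤ 15° and scale 0.95–1.05 about the tissue center, then a
    positive translation so the section stays in positive WSI coordinates."""
    theta = np.deg2rad(rng.uniform(-15.0, 15.0))
    s = rng.uniform(0.95, 1.05)
    t = rng.uniform(100.0, 500.0, size=2)
    R = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    A = s * R
    c = np.asarray(center, dtype=float)
    tvec = c - A @ c + t
    return PlanarTransform(
        matrix=np.column_stack([A, tvec]),
        model="similarity",
        source_frame_id="elemental",
        target_frame_id="wsi",
    )


_REGION_COLORS = {
    "Tumor": (190, 80, 110),
    "Stroma": (120, 150, 210),
    "Duct": (150, 110, 180),
    "Fat": (240, 220, 160),
    "Immune Cells": (110, 180, 120),
    "Interface": (200, 160, 90),
    "Lobule": (170, 120, 120),
    "Normal Fibrous Stroma": (140, 180, 190),
}
_TISSUE_COLOR = (235, 185, 205)  # eosin-ish pink
_BACKGROUND_COLOR = (255, 255, 255)


def _render_wsi(
    T: PlanarTransform,
    truth_labels: RegionLabelMap,
    tissue_truth: np.ndarray,
    spec: FixtureSpec,
) -> WSIRaster:
    """Render the fixture geometry in the WSI frame through T⁻¹, nearest."""
    er, ec = spec.elem_shape
    eps = spec.elem_pixel_size_um
    corners = np.array(
        [[0.0, 0.0], [ec * eps, 0.0], [0.0, er * eps], [ec * eps, er * eps]]
    )
    mapped = apply_to_points(T, corners)
    margin = 20.0  # µm of white border
    max_x = float(mapped[:, 0].max()) + margin
    max_y = float(mapped[:, 1].max()) + margin
    wps = spec.wsi_pixel_size_um
    rows = int(np.ceil(max_y / wps)) + 1
    cols = int(np.ceil(max_x / wps)) + 1
    Tinv = invert(T)
    palette = np.array(
        [_BACKGROUND_COLOR, _TISSUE_COLOR]
        + [
            _REGION_COLORS.get(truth_labels.label_table[rid], (128, 128, 128))
            for rid in sorted(truth_labels.label_table)
        ],
        dtype=np.uint8,
    )
    rid_order = {rid: i + 2 for i, rid in enumerate(sorted(truth_labels.label_table))}
    # class raster on the elemental grid: 0 bg, 1 tissue, 2.. regions
    cls = np.zeros(spec.elem_shape, dtype=np.int8)
    cls[tissue_truth] = 1
    for rid, pi in rid_order.items():
        cls[truth_labels.labels == rid] = pi
    pixels = np.empty((rows, cols, 3), dtype=np.uint8)
    chunk = max(1, int(4e6 // max(cols, 1)))  # bound the per-chunk working set
    xs = np.arange(cols) * wps
    for r0 in range(0, rows, chunk):
        r1 = min(r0 + chunk, rows)
        ys = np.arange(r0, r1) * wps
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        src = apply_to_points(Tinv, pts) / eps
        ci = np.round(src[:, 0]).astype(int)
        ri = np.round(src[:, 1]).astype(int)
        ok = (ci >= 0) & (ci < ec) & (ri >= 0) & (ri < er)
        k = np.zeros(pts.shape[0], dtype=np.int8)
        k[ok] = cls[ri[ok], ci[ok]]
        pixels[r0:r1] = palette[k].reshape(r1 - r0, cols, 3)
    return WSIRaster(pixels=pixels, pixel_size_um=wps, frame_id="wsi")


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate one fixture; identical specs yield bit-identical outputs."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    regions = spec.regions if spec.regions is not None else default_regions(
        spec.tissue_center_um
    )

    # region polygons as an annotation set in the ELEMENTAL frame
    elem_set = AnnotationSet(
        annotations=[
            Annotation(label=r.label, exterior=r.exterior, frame_id="elemental")
            for r in regions
        ],
        frame_id="elemental",
    )
    truth_labels = rasterize(
        elem_set, spec.elem_shape, spec.elem_pixel_size_um, frame_id="elemental"
    )
    # regions must be disjoint: total burned pixels == sum of per-region burns
    for i, a in enumerate(elem_set.annotations):
        for b in elem_set.annotations[i + 1 :]:
            if a.to_shapely().intersection(b.to_shapely()).area > 0:
                raise ValueError(
                    f"regions {a.label!r} and {b.label!r} overlap; fixture "
                    "regions must be disjoint"
                )

    er, ec = spec.elem_shape
    eps = spec.elem_pixel_size_um
    cx, cy = spec.tissue_center_um
    gy, gx = np.mgrid[0:er, 0:ec]
    tissue_truth = (
        (gx * eps - cx) ** 2 + (gy * eps - cy) ** 2
    ) <= spec.tissue_radius_um**2

    # per-element pixel draws: background, then tissue, then each region
    data = np.empty((len(spec.elements), er, ec), dtype=float)
    region_by_label = {r.label: r for r in regions}
    for k, element in enumerate(spec.elements):
        plane = np.empty((er, ec), dtype=float)
        bg = ~tissue_truth
        plane[bg] = spec.background_law.sample(rng, int(bg.sum()))
        base = tissue_truth & (truth_labels.labels == 0)
        tissue_law = spec.tissue_laws.get(element, spec.tissue_fallback_law)
        plane[base] = tissue_law.sample(rng, int(base.sum()))
        for rid in sorted(truth_labels.label_table):
            rmask = truth_labels.labels == rid
            law = region_by_label[truth_labels.label_table[rid]].laws[element]
            plane[rmask] = law.sample(rng, int(rmask.sum()))
        # instrument exports print a few decimals, not full float64; rounded
        # values also survive CSV/XLSX text round trips exactly
        data[k] = np.round(plane, 4)

    missing = np.zeros_like(data, dtype=bool)
    for row in spec.missing_rows:
        missing[:, row, :] = True
    data = np.where(missing, np.nan, data)
    emap = ElementalMap(
        data=data,
        channel_names=list(spec.elements),
        pixel_size_um=eps,
        missing_mask=missing,
        frame_id="elemental",
    )

    T = spec.true_transform or _sample_similarity(rng, spec.tissue_center_um)

    # landmarks: true correspondences inside the disc plus optional jitter
    ang = rng.uniform(0, 2 * np.pi, spec.landmark_n)
    rad = spec.tissue_radius_um * np.sqrt(rng.uniform(0.1, 1.0, spec.landmark_n))
    moving = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
    fixed = apply_to_points(T, moving)
    if spec.landmark_noise_um > 0:
        fixed = fixed + rng.normal(0.0, spec.landmark_noise_um, fixed.shape)
    landmarks = LandmarkPairs(
        fixed_xy=fixed, moving_xy=moving,
        fixed_frame_id="wsi", moving_frame_id="elemental",
    )

    annotations = transform_annotations(elem_set, T)
    wsi = _render_wsi(T, truth_labels, tissue_truth, spec)
    resolved = FixtureSpec(**{**spec.__dict__, "true_transform": T})
    return Fixture(
        wsi=wsi,
        emap=emap,
        annotations=annotations,
        landmarks=landmarks,
        true_transform=T,
        truth_labels=truth_labels,
        tissue_truth=tissue_truth,
        spec=resolved,
    )


def _format_cell(v: float) -> str:
    return "" if np.isnan(v) else repr(float(v))


def make_channel_files(
    emap: ElementalMap, out_dir: str | Path, dialect: str = "csv"
) -> list[Path]:
    """Write one per-element grid file per channel (CSV or XLSX).

    Missing entries are written as empty cells; reading the files back
    with :func:`metalmap.io.read_channel_table` and consolidating
    reproduces the map exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for ci, name in enumerate(emap.channel_names):
        plane = emap.data[ci].copy()
        plane[emap.missing_mask[ci]] = np.nan
        if dialect == "csv":
            path = out_dir / f"{name}.csv"
            lines = [
                ",".join(_format_cell(v) for v in row) for row in plane
            ]
            path.write_text("\n".join(lines) + "\n")
        elif dialect == "excel":
            import openpyxl

            path = out_dir / f"{name}.xlsx"
            wb = openpyxl.Workbook()
            ws = wb.active
            ws.title = name
            for row in plane:
                ws.append([None if np.isnan(v) else float(v) for v in row])
            wb.save(path)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        paths.append(path)
    return paths


def write_fixture_dir(
    fix: Fixture, out_dir: str | Path, dialect: str = "csv"
) -> dict[str, str]:
    """Emit a complete fixture directory of plain files.

    Contents: per-channel grid files, WSI PNG, QuPath-style GeoJSON
    annotations (WSI pixel coordinates), landmark CSV, and a truth JSON
    with the ground-truth transform and generation parameters.
    """
    from PIL import Image

    from .annotate import write_geojson
    from .register import write_landmarks_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channel_paths = make_channel_files(fix.emap, out_dir / "channels", dialect)
    wsi_path = out_dir / "wsi.png"
    Image.fromarray(fix.wsi.pixels).save(wsi_path)
    ann_path = out_dir / "annotations.geojson"
    write_geojson(fix.annotations, ann_path, fix.wsi.pixel_size_um)
    lm_path = out_dir / "landmarks.csv"
    write_landmarks_csv(fix.landmarks, lm_path)
    truth = {
        "seed": fix.spec.seed,
        "wsi_pixel_size_um": fix.spec.wsi_pixel_size_um,
        "elem_pixel_size_um": fix.spec.elem_pixel_size_um,
        "elem_shape": list(fix.spec.elem_shape),
        "tissue_center_um": list(fix.spec.tissue_center_um),
        "tissue_radius_um": fix.spec.tissue_radius_um,
        "elements": list(fix.spec.elements),
        "missing_rows": list(fix.spec.missing_rows),
        "landmark_noise_um": fix.spec.landmark_noise_um,
        "true_transform": json.loads(fix.true_transform.to_json()),
        "regions": [
            {
                "label": r.label,
                "exterior_um": np.asarray(r.exterior).tolist(),
                "laws": {
                    e: {"p_zero": l.p_zero, "gamma_shape": l.gamma_shape,
                        "gamma_mean": l.gamma_mean}
                    for e, l in r.laws.items()
                },
            }
            for r in (fix.spec.regions or default_regions(fix.spec.tissue_center_um))
        ],
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {
        "channels": str(out_dir / "channels"),
        "channel_files": [str(p) for p in channel_paths],
        "wsi": str(wsi_path),
        "annotations": str(ann_path),
        "landmarks": str(lm_path),
        "truth": str(truth_path),
    }
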