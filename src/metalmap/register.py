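"""Landmark-based planar registration between imaging modalities.

H&E whole-slide images (~0.25 µm/px) and elemental maps (1–10 µm/px)
are serial sections of the same block; a user places corresponding
fiducial points in both and the alignment is estimated as a planar
linear transform.  All transforms act on PHYSICAL coordinates in µm —
pixel rasters of wildly different resolution convert to the shared
physical frame via ``x_um = x_px * pixel_size_um`` (pixel centers,
0-based) — so estimation is decoupled from raster scale.

Model classes:

* ``affine``     — 6 d.o.f., ordinary least squares on the normal equations;
* ``similarity`` — 4 d.o.f. (rotation, isotropic scale, translation),
  centered cross-covariance SVD (orthogonal Procrustes with scale);
* ``rigid``      — 3 d.o.f., same without scale.

Reflections are rejected for rigid/similarity (determinant forced +1);
flipped sections must be handled by an explicit preprocessing flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

__all__ = [
    "LandmarkPairs",
    "PlanarTransform",
    "RankDeficiencyError",
    "estimate_transform",
    "apply_to_points",
    "invert",
    "compose",
    "registration_error",
    "resample_image",
    "read_landmarks_csv",
    "write_landmarks_csv",
]


class RankDeficiencyError(ValueError):
    """Landmark configuration cannot determine the requested model."""


@dataclass
class LandmarkPairs:
    """Paired fiducials in physical µm: ``fixed_xy[i] ~ T(moving_xy[i])``."""

    fixed_xy: np.ndarray  # (n, 2)
    moving_xy: np.ndarray  # (n, 2)
    fixed_frame_id: str = "wsi"
    moving_frame_id: str = "elemental"

    def __post_init__(self) -> None:
        self.fixed_xy = np.atleast_2d(np.asarray(self.fixed_xy, dtype=float))
        self.moving_xy = np.atleast_2d(np.asarray(self.moving_xy, dtype=float))
        if self.fixed_xy.shape != self.moving_xy.shape or self.fixed_xy.shape[1] != 2:
            raise ValueError("fixed_xy and moving_xy must both be (n, 2)")
        if self.fixed_xy.shape[0] < 1:
            raise ValueError("need at least one landmark pair")
        if not (np.isfinite(self.fixed_xy).all() and np.isfinite(self.moving_xy).all()):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.fixed_xy.shape[0]


@dataclass
class PlanarTransform:
    """2×3 matrix ``[A | t]`` mapping moving-frame (x, y) µm to fixed-frame µm."""

    matrix: np.ndarray
    model: str = "affine"
    source_frame_id: str = "elemental"
    target_frame_id: str = "wsi"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if self.model not in {"rigid", "similarity", "affine"}:
            raise ValueError(f"unknown model {self.model!r}")
        A = self.matrix[:, :2]
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("transform matrix is singular")

    @property
    def A(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def t(self) -> np.ndarray:
        return self.matrix[:, 2]

    @classmethod
    def identity(cls, frame_id: str = "frame", model: str = "affine") -> "PlanarTransform":
        return cls(
            matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            model=model,
            source_frame_id=frame_id,
            target_frame_id=frame_id,
        )

    def to_json(self, rmse_um: float | None = None) -> str:
        payload = {
            "matrix": self.matrix.tolist(),
            "model": self.model,
            "source_frame_id": self.source_frame_id,
            "target_frame_id": self.target_frame_id,
        }
        if rmse_um is not None:
            payload["rmse_um"] = rmse_um
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PlanarTransform":
        d = json.loads(text)
        return cls(
            matrix=np.asarray(d["matrix"], dtype=float),
            model=d["model"],
            source_frame_id=d["source_frame_id"],
            target_frame_id=d["target_frame_id"],
        )


def _fit_affine(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    n = moving.shape[0]
    if n < 3:
        raise RankDeficiencyError(f"affine model needs >= 3 landmark pairs, got {n}")
    X = np.column_stack([moving, np.ones(n)])
    if np.linalg.matrix_rank(X) < 3:
        raise RankDeficiencyError(
            "landmarks are collinear: affine transform is underdetermined"
        )
    coef, *_ = np.linalg.lstsq(X, fixed, rcond=None)
    return coef.T  # (2, 3)


def _fit_procrustes(
    moving: np.ndarray, fixed: np.ndarray, with_scale: bool
) -> np.ndarray:
    n = moving.shape[0]
    if n < 2:
        raise RankDeficiencyError("rigid/similarity models need >= 2 landmark pairs")
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    Xm = moving - mu_m
    Xf = fixed - mu_f
    var_m = (Xm**2).sum() / n
    if var_m < 1e-18:
        raise RankDeficiencyError(
            "landmarks are coincident: rotation is underdetermined"
        )
    C = Xf.T @ Xm / n  # cross-covariance, fixed x moving
    U, D, Vt = np.linalg.svd(C)
    # disallow reflection: force det(R) = +1
    S = np.eye(2)
    if np.linalg.det(U @ Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    if with_scale:
        s = np.trace(np.diag(D) @ S) / var_m
        if not s > 0:
            raise RankDeficiencyError("degenerate landmarks: non-positive scale")
    else:
        s = 1.0
    A = s * R
    t = mu_f - A @ mu_m
    return np.column_stack([A, t])


def estimate_transform(pairs: LandmarkPairs, model: str = "affine") -> PlanarTransform:
    """Least-squares fit of ``T`` minimizing Σ‖T(moving_i) − fixed_i‖²."""
    if model == "affine":
        M = _fit_affine(pairs.moving_xy, pairs.fixed_xy)
    elif model in {"similarity", "rigid"}:
        M = _fit_procrustes(pairs.moving_xy, pairs.fixed_xy, model == "similarity")
    else:
        raise ValueError(f"unknown model {model!r}")
    return PlanarTransform(
        matrix=M,
        model=model,
        source_frame_id=pairs.moving_frame_id,
        target_frame_id=pairs.fixed_frame_id,
    )


def apply_to_points(T: PlanarTransform, pts: np.ndarray) -> np.ndarray:
    """Map an (n, 2) array of (x, y) points through ``T``."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    return pts @ T.A.T + T.t


def invert(T: PlanarTransform) -> PlanarTransform:
    Ainv = np.linalg.inv(T.A)
    return PlanarTransform(
        matrix=np.column_stack([Ainv, -Ainv @ T.t]),
        model=T.model,
        source_frame_id=T.target_frame_id,
        target_frame_id=T.source_frame_id,
    )


def compose(T2: PlanarTransform, T1: PlanarTransform) -> PlanarTransform:
    """Return the transform applying ``T1`` first, then ``T2``."""
    if T1.target_frame_id != T2.source_frame_id:
        raise ValueError(
            f"frame mismatch: {T1.target_frame_id!r} -> {T2.source_frame_id!r}"
        )
    A = T2.A @ T1.A
    t = T2.A @ T1.t + T2.t
    model = T1.model if T1.model == T2.model else "affine"
    return PlanarTransform(
        matrix=np.column_stack([A, t]),
        model=model,
        source_frame_id=T1.source_frame_id,
        target_frame_id=T2.target_frame_id,
    )


def registration_error(T: PlanarTransform, pairs: LandmarkPairs) -> dict:
    """Per-landmark residuals ‖T(moving) − fixed‖ and their RMSE, in µm."""
    mapped = apply_to_points(T, pairs.moving_xy)
    residuals = np.linalg.norm(mapped - pairs.fixed_xy, axis=1)
    return {
        "rmse_um": float(np.sqrt(np.mean(residuals**2))),
        "residuals_um": residuals.tolist(),
    }


def resample_image(
    img: np.ndarray,
    pixel_size_um: float,
    T: PlanarTransform,
    out_shape: tuple[int, int],
    out_pixel_size_um: float,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``img`` (source frame) onto a target-frame grid.

    ``T`` maps source physical coordinates to target physical
    coordinates; each output pixel (r, c) is sampled at
    ``T⁻¹((c, r) * out_pixel_size_um)``.  Returns ``(out, out_missing)``
    where out-of-bounds samples are 0 and flagged missing.  Label and
    mask images must use ``nearest``.
    """
    from scipy.ndimage import map_coordinates

    if not out_pixel_size_um > 0:
        raise ValueError("out_pixel_size_um must be positive")
    if interpolation not in {"nearest", "bilinear"}:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    img = np.asarray(img)
    rows, cols = out_shape
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    target_xy = np.column_stack([cc.ravel(), rr.ravel()]) * float(out_pixel_size_um)
    src_xy = apply_to_points(invert(T), target_xy) / float(pixel_size_um)
    x = src_xy[:, 0].reshape(rows, cols)
    y = src_xy[:, 1].reshape(rows, cols)
    h, w = img.shape[:2]
    if interpolation == "nearest":
        oob = (x < -0.5) | (x > w - 0.5) | (y < -0.5) | (y > h - 0.5)
    else:
        oob = (x < 0) | (x > w - 1) | (y < 0) | (y > h - 1)
    order = 0 if interpolation == "nearest" else 1
    coords = np.stack([y.ravel(), x.ravel()])

    def _sample(plane: np.ndarray) -> np.ndarray:
        out = map_coordinates(
            plane.astype(float), coords, order=order, mode="constant", cval=0.0
        ).reshape(rows, cols)
        out[oob] = 0.0
        return out

    if img.ndim == 2:
        out = _sample(img)
        if img.dtype == bool:
            out = out > 0.5
        elif np.issubdtype(img.dtype, np.integer):
            out = np.round(out).astype(img.dtype)
    else:
        out = np.stack([_sample(img[..., k]) for k in range(img.shape[2])], axis=-1)
        if np.issubdtype(img.dtype, np.integer):
            out = np.clip(np.round(out), 0, 255).astype(img.dtype)
    return out, oob


def write_landmarks_csv(pairs: LandmarkPairs, path: str | Path) -> None:
    """CSV with columns fixed_x, fixed_y, moving_x, moving_y (µm)."""
    import pandas as pd

    pd.DataFrame(
        {
            "fixed_x": pairs.fixed_xy[:, 0],
            "fixed_y": pairs.fixed_xy[:, 1],
            "moving_x": pairs.moving_xy[:, 0],
            "moving_y": pairs.moving_xy[:, 1],
        }
    ).to_csv(path, index=False)


def read_landmarks_csv(
    path: str | Path, fixed_frame_id: str = "wsi", moving_frame_id: str = "elemental"
) -> LandmarkPairs:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"fixed_x", "fixed_y", "moving_x", "moving_y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"landmark CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return LandmarkPairs(
        fixed_xy=df[["fixed_x", "fixed_y"]].to_numpy(float),
        moving_xy=df[["moving_x", "moving_y"]].to_numpy(float),
        fixed_frame_id=fixed_frame_id,
        moving_frame_id=moving_frame_id,
    )
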