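"""DLT camera model, calibration, triangulation and uncertainty statistics.

The projection model maps object space (x, y, z) to image space (u, v)
through 11 linear parameters L1..L11 with the denominator normalized as
``L9*x + L10*y + L11*z + 1``, plus a polynomial lens-distortion term
(radial k1, k2; tangential p1, p2) evaluated at the undistorted
projection in coordinates normalized about the principal point.

Uncertainty of a reconstructed point is the camera-mean of squared image
residuals; per-marker and whole-set summaries follow by averaging over
frames and markers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CameraModel",
    "MarkerObservation",
    "UncertaintyReport",
    "DegeneratePointError",
    "RankDeficiencyError",
    "IllConditionedWarning",
    "MissingObservationError",
    "dlt_project",
    "dlt_calibrate",
    "triangulate",
    "uncertainty_stats",
    "refine_distortion",
    "observations_to_frame",
    "load_cameras",
    "save_cameras",
]


class DegeneratePointError(ValueError):
    """Point lies on (or numerically at) the camera's degeneracy plane."""


class RankDeficiencyError(ValueError):
    """Calibration design matrix has rank below 11."""


class IllConditionedWarning(UserWarning):
    """Triangulation geometry is near-degenerate (near-parallel rays)."""


@dataclass(frozen=True)
class CameraModel:
    """11-parameter DLT camera with optional polynomial distortion."""

    L: np.ndarray  # (11,)
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    principal_point: tuple[float, float] = (0.0, 0.0)
    image_size: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "L", np.asarray(self.L, dtype=float).reshape(11))
        for name in ("k1", "k2", "p1", "p2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"distortion coefficient {name} must be finite")

    @property
    def norm_scale(self) -> float:
        """Pixel scale used to normalize distortion coordinates."""
        if self.image_size is not None:
            return float(self.image_size[0]) / 2.0
        return 1.0

    def has_distortion(self) -> bool:
        return any(abs(c) > 0 for c in (self.k1, self.k2, self.p1, self.p2))

    def to_dict(self) -> dict:
        return {
            "L": self.L.tolist(),
            "k1": self.k1,
            "k2": self.k2,
            "p1": self.p1,
            "p2": self.p2,
            "u0": self.principal_point[0],
            "v0": self.principal_point[1],
            "width": None if self.image_size is None else self.image_size[0],
            "height": None if self.image_size is None else self.image_size[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        size = None
        if d.get("width") is not None:
            size = (d["width"], d["height"])
        return cls(
            L=np.asarray(d["L"], dtype=float),
            k1=d.get("k1", 0.0),
            k2=d.get("k2", 0.0),
            p1=d.get("p1", 0.0),
            p2=d.get("p2", 0.0),
            principal_point=(d.get("u0", 0.0), d.get("v0", 0.0)),
            image_size=size,
        )


@dataclass(frozen=True)
class MarkerObservation:
    """A single 2D measurement: camera i, frame j, marker k, pixel (u, v)."""

    camera: int
    frame: int
    marker: int
    uv: tuple[float, float]


@dataclass
class UncertaintyReport:
    """Reconstruction uncertainty summaries.

    ``epsilon_point`` is the per-(frame, marker) table; ``epsilon_single``
    the per-marker average over cameras and frames; ``epsilon_multi`` the
    grand average, which is identically the marker-mean of
    ``epsilon_single``.
    """

    epsilon_point: np.ndarray  # (f, p)
    epsilon_single: np.ndarray  # (p,)
    epsilon_multi: float
    c: int
    f: int
    p: int


def _linear_uv(camera: CameraModel, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = camera.L
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    den = L[8] * x + L[9] * y + L[10] * z + 1.0
    if np.any(np.abs(den) < 1e-12):
        raise DegeneratePointError("point on the camera's degeneracy plane")
    u = (L[0] * x + L[1] * y + L[2] * z + L[3]) / den
    v = (L[4] * x + L[5] * y + L[6] * z + L[7]) / den
    return u, v


def _distortion_delta(
    camera: CameraModel, u_lin: np.ndarray, v_lin: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    s = camera.norm_scale
    u0, v0 = camera.principal_point
    xn = (u_lin - u0) / s
    yn = (v_lin - v0) / s
    r2 = xn * xn + yn * yn
    radial = camera.k1 * r2 + camera.k2 * r2 * r2
    du = s * (xn * radial + 2.0 * camera.p1 * xn * yn + camera.p2 * (r2 + 2.0 * xn * xn))
    dv = s * (yn * radial + camera.p1 * (r2 + 2.0 * yn * yn) + 2.0 * camera.p2 * xn * yn)
    return du, dv


def dlt_project(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project object-space points to pixels (distortion included).

    Accepts a single 3-vector or an (N, 3) array; returns matching shape
    with a trailing dimension of 2.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    u, v = _linear_uv(camera, pts)
    du, dv = _distortion_delta(camera, u, v)
    uv = np.stack([u + du, v + dv], axis=-1)
    return uv[0] if single else uv


def _undistort_uv(camera: CameraModel, uv: np.ndarray, iters: int = 25) -> np.ndarray:
    """Invert the distortion map: find uv_lin with uv_lin + delta(uv_lin) = uv."""
    if not camera.has_distortion():
        return np.asarray(uv, dtype=float)
    uv = np.asarray(uv, dtype=float)
    u_lin, v_lin = uv[..., 0].copy(), uv[..., 1].copy()
    for _ in range(iters):
        du, dv = _distortion_delta(camera, u_lin, v_lin)
        u_lin = uv[..., 0] - du
        v_lin = uv[..., 1] - dv
    return np.stack([u_lin, v_lin], axis=-1)


def dlt_calibrate(
    control_points: list[tuple[np.ndarray, tuple[float, float]]],
    image_size: tuple[float, float] | None = None,
) -> CameraModel:
    """Linear DLT calibration from (object point, pixel) correspondences.

    Needs at least six non-coplanar points. Distortion is left at zero;
    the principal point is derived from the recovered L.
    """
    if len(control_points) < 6:
        raise RankDeficiencyError(
            f"need at least 6 control points, got {len(control_points)}"
        )
    A = np.zeros((2 * len(control_points), 11))
    b = np.zeros(2 * len(control_points))
    for i, (X, uv) in enumerate(control_points):
        x, y, z = np.asarray(X, dtype=float)
        u, v = uv
        A[2 * i] = [x, y, z, 1, 0, 0, 0, 0, -u * x, -u * y, -u * z]
        A[2 * i + 1] = [0, 0, 0, 0, x, y, z, 1, -v * x, -v * y, -v * z]
        b[2 * i] = u
        b[2 * i + 1] = v
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, float(np.abs(A).max()))) < 11:
        raise RankDeficiencyError(
            "design matrix rank < 11 (too few or coplanar control points)"
        )
    L, *_ = np.linalg.lstsq(A, b, rcond=None)
    w2 = L[8] ** 2 + L[9] ** 2 + L[10] ** 2
    if w2 > 0:
        u0 = (L[0] * L[8] + L[1] * L[9] + L[2] * L[10]) / w2
        v0 = (L[4] * L[8] + L[5] * L[9] + L[6] * L[10]) / w2
    else:
        u0 = v0 = 0.0
    return CameraModel(L=L, principal_point=(u0, v0), image_size=image_size)


def triangulate(
    cameras: list[CameraModel],
    obs: list[tuple[float, float]],
    polish: bool = True,
) -> tuple[np.ndarray, float]:
    """Reconstruct one 3D point from per-camera pixel observations.

    Solves the linear rearrangement of the projection equations on
    distortion-corrected pixels, then (by default) polishes with a
    nonlinear least-squares pass on the full distorted model. Returns the
    point and the achieved uncertainty, the camera-mean of squared pixel
    residuals.
    """
    if len(cameras) < 2 or len(obs) < 2:
        raise ValueError("triangulation is under-determined with fewer than 2 cameras")
    if len(cameras) != len(obs):
        raise ValueError("cameras and observations must align")
    A = np.zeros((2 * len(cameras), 3))
    b = np.zeros(2 * len(cameras))
    for i, (cam, uv) in enumerate(zip(cameras, obs)):
        u, v = _undistort_uv(cam, np.asarray(uv, dtype=float))
        L = cam.L
        A[2 * i] = [L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]]
        A[2 * i + 1] = [L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]]
        b[2 * i] = u - L[3]
        b[2 * i + 1] = v - L[7]
    cond = np.linalg.cond(A)
    if cond > 1e10:
        warnings.warn(
            f"near-parallel rays: condition number {cond:.3g}", IllConditionedWarning
        )
    X, *_ = np.linalg.lstsq(A, b, rcond=None)

    def residuals(p: np.ndarray) -> np.ndarray:
        out = np.empty(2 * len(cameras))
        for i, (cam, uv) in enumerate(zip(cameras, obs)):
            pred = dlt_project(cam, p)
            out[2 * i] = uv[0] - pred[0]
            out[2 * i + 1] = uv[1] - pred[1]
        return out

    if polish:
        sol = least_squares(residuals, X, method="lm", xtol=1e-14, ftol=1e-14)
        X = sol.x
    res = residuals(X)
    eps = float(np.sum(res**2) / len(cameras))
    return X, eps


class MissingObservationError(ValueError):
    """Observation table lacks required (camera, frame, marker) rows."""

    def __init__(self, missing: list[tuple[int, int, int]]):
        self.missing = missing
        preview = ", ".join(map(str, missing[:10]))
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        super().__init__(f"missing observations for (camera, frame, marker): {preview}{more}")


def observations_to_frame(observations) -> pd.DataFrame:
    """Normalize observations into a DataFrame (camera, frame, marker, u, v)."""
    if isinstance(observations, pd.DataFrame):
        return observations
    rows = [
        {
            "camera": o.camera,
            "frame": o.frame,
            "marker": o.marker,
            "u": o.uv[0],
            "v": o.uv[1],
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


def uncertainty_stats(
    cameras: list[CameraModel],
    observations,
    reconstructions: np.ndarray,
) -> UncertaintyReport:
    """Per-point, per-marker and whole-set uncertainty of a reconstruction.

    ``reconstructions`` has shape (f, p, 3). The observation table must
    contain every (camera, frame, marker) combination; residuals are the
    observed pixels minus the reprojection of the reconstructed points.
    """
    df = observations_to_frame(observations)
    recon = np.asarray(reconstructions, dtype=float)
    f, p, _ = recon.shape
    c = len(cameras)
    lut = {
        (int(r.camera), int(r.frame), int(r.marker)): (r.u, r.v)
        for r in df.itertuples()
    }
    missing = [
        (i, j, k)
        for i in range(c)
        for j in range(f)
        for k in range(p)
        if (i, j, k) not in lut
    ]
    if missing:
        raise MissingObservationError(missing)
    sq = np.zeros((c, f, p))
    for i, cam in enumerate(cameras):
        pred = dlt_project(cam, recon.reshape(-1, 3)).reshape(f, p, 2)
        for j in range(f):
            for k in range(p):
                u, v = lut[(i, j, k)]
                du = u - pred[j, k, 0]
                dv = v - pred[j, k, 1]
                sq[i, j, k] = du * du + dv * dv
    eps_point = sq.sum(axis=0) / c  # (f, p)
    eps_single = sq.sum(axis=(0, 1)) / (c * f)  # (p,)
    eps_multi = float(sq.sum() / (c * f * p))
    return UncertaintyReport(
        epsilon_point=eps_point,
        epsilon_single=eps_single,
        epsilon_multi=eps_multi,
        c=c,
        f=f,
        p=p,
    )


def _reprojection_rms(camera: CameraModel, control_points) -> float:
    pts = np.array([np.asarray(X, dtype=float) for X, _ in control_points])
    uv_obs = np.array([uv for _, uv in control_points], dtype=float)
    pred = dlt_project(camera, pts)
    return float(np.sqrt(np.mean((pred - uv_obs) ** 2)))


def refine_distortion(
    camera: CameraModel,
    control_points: list[tuple[np.ndarray, tuple[float, float]]],
    max_iters: int = 300,
    tol: float = 1e-12,
    central_fraction: float = 0.5,
    return_trace: bool = False,
):
    """Two-step iterative distortion refinement.

    Alternates: (1) re-fit L from points whose observations fall in the
    central ``central_fraction`` box of the image, where distortion is
    small, after subtracting the current distortion estimate; (2) fit
    (k1, k2, p1, p2) linearly on all points holding L fixed. Iterates
    until the all-point reprojection RMS improves by less than ``tol``;
    the RMS trace is non-increasing by construction (a worsening step is
    reverted).
    """
    if camera.image_size is not None:
        w, h = camera.image_size
        cx, cy = w / 2.0, h / 2.0
        hw, hh = central_fraction * w / 2.0, central_fraction * h / 2.0
    else:
        uvs = np.array([uv for _, uv in control_points], dtype=float)
        lo, hi = uvs.min(axis=0), uvs.max(axis=0)
        cx, cy = (lo + hi) / 2.0
        hw, hh = central_fraction * (hi - lo) / 2.0
    central = [
        (X, uv)
        for X, uv in control_points
        if abs(uv[0] - cx) <= hw and abs(uv[1] - cy) <= hh
    ]
    if not central:
        raise ValueError("no control points fall in the central image region")

    current = camera
    best = current
    best_rms = _reprojection_rms(current, control_points)
    trace = [best_rms]
    for _ in range(max_iters):
        # step 1: re-fit L on central points, removing current distortion
        corrected = []
        for X, uv in central:
            uv_lin = _undistort_uv(current, np.asarray(uv, dtype=float))
            corrected.append((X, (float(uv_lin[0]), float(uv_lin[1]))))
        lin = dlt_calibrate(corrected, image_size=camera.image_size)
        # principal point re-derived from the refit L: it sharpens as the
        # distortion estimate improves, which is what makes the alternation
        # contract toward the true parameters
        current = replace(
            current,
            L=lin.L,
            principal_point=lin.principal_point,
        )
        # step 2: fit distortion linearly on all points, L fixed
        s = current.norm_scale
        u0, v0 = current.principal_point
        rows, rhs = [], []
        for X, uv in control_points:
            u_lin, v_lin = _linear_uv(current, np.atleast_2d(np.asarray(X, float)))
            u_lin, v_lin = float(u_lin[0]), float(v_lin[0])
            xn, yn = (u_lin - u0) / s, (v_lin - v0) / s
            r2 = xn * xn + yn * yn
            rows.append([s * xn * r2, s * xn * r2 * r2, s * 2 * xn * yn, s * (r2 + 2 * xn * xn)])
            rhs.append(uv[0] - u_lin)
            rows.append([s * yn * r2, s * yn * r2 * r2, s * (r2 + 2 * yn * yn), s * 2 * xn * yn])
            rhs.append(uv[1] - v_lin)
        coeffs, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        current = replace(
            current, k1=float(coeffs[0]), k2=float(coeffs[1]),
            p1=float(coeffs[2]), p2=float(coeffs[3]),
        )
        rms = _reprojection_rms(current, control_points)
        if rms > best_rms:
            current = best  # revert worsening step
            break
        trace.append(rms)
        improved = best_rms - rms
        best, best_rms = current, rms
        if improved < tol or rms < 1e-10:  # converged or at numerical floor
            break
    if return_trace:
        return best, trace
    return best


def save_cameras(cameras: list[CameraModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in cameras], fh, indent=2)


def load_cameras(path) -> list[CameraModel]:
    with open(path) as fh:
        return [CameraModel.from_dict(d) for d in json.load(fh)]
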