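"""Camera models and multi-view triangulation.

A :class:`CameraModel` is the standard pinhole camera with radial
(k1, k2, k3) and tangential (p1, p2) lens distortion; extrinsics are an
axis-angle rotation and a translation mapping world coordinates into the
camera frame.  A :class:`CameraRig` is an ordered, named collection of
at least two such cameras sharing a world frame.

Pixel conventions: x is the column (width) axis, y the row (height) axis,
origin at the image top-left, with continuous subpixel values at pixel
centers.  This matches the heatmap grid used by :mod:`mveks.trainaux`.

Triangulation is the homogeneous DLT on undistorted normalized rays,
averaged over all camera pairs.  Invalid entries (behind-camera points,
degenerate ray pairs, non-converged undistortion) are carried as NaN and
excluded from reductions rather than raised.
"""

from __future__ import annotations

import itertools
import tomllib
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CameraModel",
    "CameraRig",
    "project",
    "undistort",
    "triangulate_pair",
    "triangulate_multiview",
    "reprojection_error",
    "read_calibration",
    "write_calibration",
]


@dataclass(frozen=True)
class CameraModel:
    """One calibrated view: intrinsics, distortion, extrinsics."""

    name: str
    focal: tuple[float, float]  # (fx, fy), pixels
    principal: tuple[float, float]  # (cx, cy), pixels
    distortion: tuple[float, float, float, float, float] = (0.0,) * 5  # k1 k2 p1 p2 k3
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # axis-angle, radians
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # world units
    size: tuple[int, int] | None = None  # (width, height), optional

    def __post_init__(self) -> None:
        fx, fy = self.focal
        if not (fx > 0 and fy > 0):
            raise ValueError(f"camera {self.name!r}: focal lengths must be positive")
        R = self.rotation_matrix
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ValueError(f"camera {self.name!r}: rotation is not proper orthogonal")

    @cached_property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(np.asarray(self.rotation, dtype=float)).as_matrix()

    @cached_property
    def _translation_vector(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        fx, fy = self.focal
        cx, cy = self.principal
        return np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])

    @classmethod
    def from_matrix(cls, name, matrix, distortion, rotation, translation, size=None):
        K = np.asarray(matrix, dtype=float)
        return cls(
            name=name,
            focal=(float(K[0, 0]), float(K[1, 1])),
            principal=(float(K[0, 2]), float(K[1, 2])),
            distortion=tuple(float(d) for d in distortion),
            rotation=tuple(float(r) for r in rotation),
            translation=tuple(float(t) for t in translation),
            size=None if size is None else (int(size[0]), int(size[1])),
        )


@dataclass(frozen=True)
class CameraRig:
    """Ordered list of V >= 2 uniquely named cameras in a shared world frame."""

    cameras: tuple[CameraModel, ...]

    def __post_init__(self) -> None:
        if len(self.cameras) < 2:
            raise ValueError("a rig needs at least two cameras")
        names = [c.name for c in self.cameras]
        if len(set(names)) != len(names):
            raise ValueError(f"camera names must be unique, got {names}")
        object.__setattr__(self, "cameras", tuple(self.cameras))

    def __len__(self) -> int:
        return len(self.cameras)

    def __iter__(self):
        return iter(self.cameras)

    def __getitem__(self, i: int) -> CameraModel:
        return self.cameras[i]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.cameras]


def _to_camera_frame(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    return points @ camera.rotation_matrix.T + camera._translation_vector


def _distort_normalized(camera: CameraModel, xy: np.ndarray) -> np.ndarray:
    """Apply the distortion polynomial to ideal normalized coordinates."""
    k1, k2, p1, p2, k3 = camera.distortion
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def project(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Project world points (..., 3) to pixel coordinates (..., 2).

    Points at or behind the camera plane (z_cam <= 0) come back as NaN
    rather than raising; NaN inputs propagate.
    """
    points = np.asarray(points, dtype=float)
    cam_pts = _to_camera_frame(camera, points)
    z = cam_pts[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        xy = cam_pts[..., :2] / z[..., None]
    xy = np.where(z[..., None] > 0, xy, np.nan)
    xyd = _distort_normalized(camera, xy)
    fx, fy = camera.focal
    cx, cy = camera.principal
    return np.stack([fx * xyd[..., 0] + cx, fy * xyd[..., 1] + cy], axis=-1)


def undistort(
    camera: CameraModel,
    pixels: np.ndarray,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> np.ndarray:
    """Map pixel coordinates (..., 2) to ideal normalized coordinates.

    Inverts the distortion polynomial by fixed-point iteration starting
    from the distorted normalized coordinates.  Entries that fail to
    converge within ``max_iter`` iterations are returned as NaN.
    """
    pixels = np.asarray(pixels, dtype=float)
    fx, fy = camera.focal
    cx, cy = camera.principal
    xd = (pixels[..., 0] - cx) / fx
    yd = (pixels[..., 1] - cy) / fy
    target = np.stack([xd, yd], axis=-1)
    if not any(camera.distortion):
        return target
    xy = target.copy()
    k1, k2, p1, p2, k3 = camera.distortion
    converged = np.zeros(xy.shape[:-1], dtype=bool)
    for _ in range(max_iter):
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        with np.errstate(invalid="ignore", divide="ignore"):
            new = (target - np.stack([dx, dy], axis=-1)) / radial[..., None]
        step = np.nanmax(np.abs(new - xy), axis=-1)
        converged = step < tol
        xy = new
        if np.all(converged | ~np.isfinite(step)):
            break
    xy = np.where(converged[..., None], xy, np.nan)
    return xy


def _normalized_projection_matrix(camera: CameraModel) -> np.ndarray:
    """[R | t] — projection matrix in undistorted normalized coordinates."""
    R = camera.rotation_matrix
    t = np.asarray(camera.translation, dtype=float)
    return np.hstack([R, t[:, None]])


def triangulate_pair(
    cam_a: CameraModel,
    cam_b: CameraModel,
    pts_a: np.ndarray,
    pts_b: np.ndarray,
) -> np.ndarray:
    """DLT triangulation of pixel observations from two views.

    Returns world points (..., 3); NaN where either observation is
    invalid or the geometry is degenerate (e.g. coincident rays).
    """
    na = undistort(cam_a, np.asarray(pts_a, dtype=float))
    nb = undistort(cam_b, np.asarray(pts_b, dtype=float))
    Pa = _normalized_projection_matrix(cam_a)
    Pb = _normalized_projection_matrix(cam_b)
    flat_a = na.reshape(-1, 2)
    flat_b = nb.reshape(-1, 2)
    out = np.full((flat_a.shape[0], 3), np.nan)
    for i, (a, b) in enumerate(zip(flat_a, flat_b)):
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            continue
        A = np.stack(
            [
                a[0] * Pa[2] - Pa[0],
                a[1] * Pa[2] - Pa[1],
                b[0] * Pb[2] - Pb[0],
                b[1] * Pb[2] - Pb[1],
            ]
        )
        _, s, vt = np.linalg.svd(A)
        # two coincident rays leave a 2D null space: s[2] ~ 0 relative to s[0]
        if s[2] < 1e-9 * s[0]:
            continue
        X = vt[-1]
        if abs(X[3]) < 1e-12:
            continue
        out[i] = X[:3] / X[3]
    return out.reshape(na.shape[:-1] + (3,))


def triangulate_multiview(
    rig: CameraRig,
    observations: np.ndarray,
    validity: np.ndarray | None = None,
) -> np.ndarray:
    """Triangulate per-view pixel observations [V, ..., 2] to world points.

    Computes the DLT solution for every unordered pair of valid views and
    averages.  Keypoints with fewer than two valid views are NaN.
    """
    observations = np.asarray(observations, dtype=float)
    V = len(rig)
    if observations.shape[0] != V:
        raise ValueError(
            f"observations have leading dim {observations.shape[0]}, rig has {V} views"
        )
    valid = np.all(np.isfinite(observations), axis=-1)
    if validity is not None:
        valid &= np.asarray(validity, dtype=bool)
    obs = np.where(valid[..., None], observations, np.nan)
    acc = np.zeros(observations.shape[1:-1] + (3,))
    cnt = np.zeros(observations.shape[1:-1])
    for i, j in itertools.combinations(range(V), 2):
        pts = triangulate_pair(rig[i], rig[j], obs[i], obs[j])
        ok = np.all(np.isfinite(pts), axis=-1)
        acc[ok] += pts[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt[..., None]
    mean[cnt == 0] = np.nan
    return mean


def reprojection_error(
    rig: CameraRig,
    observations: np.ndarray,
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel distance between observations [V, ..., 2] and reprojections.

    Returns ``(per_view, mean_over_views)``; invalid entries are NaN and
    excluded from the mean.
    """
    observations = np.asarray(observations, dtype=float)
    points = np.asarray(points, dtype=float)
    per_view = np.full(observations.shape[:-1], np.nan)
    for v, cam in enumerate(rig):
        proj = project(cam, points)
        per_view[v] = np.linalg.norm(observations[v] - proj, axis=-1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_view, axis=0)
    return per_view, mean


def project_jacobian(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`project` w.r.t. the world point.

    Returns (..., 2, 3); rows are d(u, v)/d(X, Y, Z).  Entries for points
    at or behind the camera plane are NaN.
    """
    points = np.asarray(points, dtype=float)
    R = camera.rotation_matrix
    cam_pts = _to_camera_frame(camera, points)
    X, Y, Z = cam_pts[..., 0], cam_pts[..., 1], cam_pts[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        x = X / Z
        y = Y / Z
        inv_z = 1.0 / Z
    bad = ~(Z > 0)
    # d(x, y)/d(cam point)
    zeros = np.zeros_like(x)
    J_norm = np.stack(
        [
            np.stack([inv_z, zeros, -x * inv_z], axis=-1),
            np.stack([zeros, inv_z, -y * inv_z], axis=-1),
        ],
        axis=-2,
    )
    # d(distorted)/d(x, y)
    k1, k2, p1, p2, k3 = camera.distortion
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    dradial_dr2 = k1 + 2.0 * k2 * r2 + 3.0 * k3 * r2**2
    dxd_dx = radial + x * dradial_dr2 * 2.0 * x + 2.0 * p1 * y + 6.0 * p2 * x
    dxd_dy = x * dradial_dr2 * 2.0 * y + 2.0 * p1 * x + 2.0 * p2 * y
    dyd_dx = y * dradial_dr2 * 2.0 * x + 2.0 * p1 * x + 2.0 * p2 * y
    dyd_dy = radial + y * dradial_dr2 * 2.0 * y + 6.0 * p1 * y + 2.0 * p2 * x
    J_dist = np.stack(
        [
            np.stack([dxd_dx, dxd_dy], axis=-1),
            np.stack([dyd_dx, dyd_dy], axis=-1),
        ],
        axis=-2,
    )
    fx, fy = camera.focal
    K = np.array([[fx, 0.0], [0.0, fy]])
    J = K @ J_dist @ J_norm @ R
    J = np.where(bad[..., None, None], np.nan, J)
    return J


# ---------------------------------------------------------------------------
# calibration files


def read_calibration(path) -> CameraRig:
    """Read a TOML calibration file: one table per camera with keys
    ``matrix`` (3x3 row-major), ``distortions`` (k1 k2 p1 p2 k3),
    ``rotation`` (axis-angle), ``translation``, ``name`` and optional
    ``size`` (width, height).  Extra keys are tolerated."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cams = []
    for key, tbl in data.items():
        if not isinstance(tbl, dict):
            continue
        cams.append(
            CameraModel.from_matrix(
                name=str(tbl.get("name", key)),
                matrix=tbl["matrix"],
                distortion=tbl["distortions"],
                rotation=tbl["rotation"],
                translation=tbl["translation"],
                size=tbl.get("size"),
            )
        )
    return CameraRig(tuple(cams))


def _fmt_toml_value(v) -> str:
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_fmt_toml_value(x) for x in v) + "]"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return repr(float(v))


def write_calibration(path, rig: CameraRig) -> None:
    """Write the TOML calibration dialect read by :func:`read_calibration`."""
    lines = []
    for cam in rig:
        lines.append(f"[{cam.name}]")
        lines.append(f"name = {_fmt_toml_value(cam.name)}")
        K = cam.intrinsic_matrix
        lines.append(f"matrix = {_fmt_toml_value([list(row) for row in K])}")
        lines.append(f"distortions = {_fmt_toml_value(cam.distortion)}")
        lines.append(f"rotation = {_fmt_toml_value(cam.rotation)}")
        lines.append(f"translation = {_fmt_toml_value(cam.translation)}")
        if cam.size is not None:
            lines.append(f"size = {_fmt_toml_value(cam.size)}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
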