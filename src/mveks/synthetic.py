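"""Synthetic multi-camera scenes for exercising the full toolkit.

The generator emulates the smoother's own generative assumptions plus
the failure modes the inflation procedure targets: a latent 3D center
performs a Gaussian random walk with known step covariance s_true * E_true,
keypoints are a rigid constellation of fixed random offsets around it,
cameras on a circle looking at the origin project the keypoints to
pixels, and an M-member ensemble adds i.i.d. Gaussian pixel noise per
member.  Occlusion segments can replace a (view, keypoint, frame-range)
block either by a common displaced value with near-zero member spread
("confidently wrong": the ensemble variance is misleadingly small) or by
independent large-noise values (an honest, high-variance failure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsemblePredictions, aggregate
from .geometry import CameraModel, CameraRig, project, reprojection_error, triangulate_multiview

__all__ = ["OcclusionSpec", "SceneSpec", "SyntheticScene", "make_rig", "simulate_scene", "evaluate"]

# member spread (pixels) used for member-correlated "confidently wrong"
# segments: small enough that the ensemble variance looks trustworthy
CONFIDENT_WRONG_SPREAD = 0.01


@dataclass(frozen=True)
class OcclusionSpec:
    """One corrupted segment.

    displacement : pixel offset applied to the truth (member-correlated
        mode) or the noise scale of independent large-noise corruption.
    member_correlated : True = all members agree on the wrong value.
    """

    view: int
    keypoint: int
    start: int
    stop: int  # exclusive
    displacement: tuple[float, float] = (30.0, 0.0)
    member_correlated: bool = True
    spread: float | None = None  # member spread around the wrong value;
    # None = CONFIDENT_WRONG_SPREAD (misleadingly confident ensemble)


@dataclass
class SceneSpec:
    """Full description of a synthetic scene.

    Defaults give a three-camera, two-keypoint, 200-frame scene with a
    three-member ensemble (the ensemble size used throughout the study
    conditions this generator emulates) and moderate pixel noise.
    """

    n_views: int = 3
    n_keypoints: int = 2
    n_frames: int = 200
    n_members: int = 3
    s_true: float = 1.0
    process_cov: np.ndarray | float = 0.02**2  # E_true; scalar = isotropic 3x3
    sigma_obs: float = 3.0  # member pixel noise, std
    hetero: float = 0.0  # lognormal spread of per-entry noise scales
    constellation_radius: float = 0.5  # keypoint offsets around the center, world units
    rig_radius: float = 5.0
    focal: float = 300.0
    distortion_level: float = 0.0
    occlusions: list[OcclusionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_views, self.n_keypoints, self.n_frames, self.n_members) < 1:
            raise ValueError("all counts must be positive")
        for occ in self.occlusions:
            if not (0 <= occ.start <= occ.stop <= self.n_frames):
                raise ValueError(f"occlusion frames {occ.start}:{occ.stop} outside [0, {self.n_frames})")
            if not (0 <= occ.view < self.n_views and 0 <= occ.keypoint < self.n_keypoints):
                raise ValueError("occlusion view/keypoint out of range")

    @property
    def process_cov_matrix(self) -> np.ndarray:
        E = np.asarray(self.process_cov, dtype=float)
        if E.ndim == 0:
            return float(E) * np.eye(3)
        return E


@dataclass
class SyntheticScene:
    rig: CameraRig
    truth3d: np.ndarray  # [T, K, 3]
    truth2d: np.ndarray  # [T, V, K, 2]
    ensemble: EnsemblePredictions
    corrupted: list  # (frame, view, keypoint) entries, exhaustive
    spec: SceneSpec

    def observations(self, ddof: int = 1):
        """Aggregate the ensemble into smoother input."""
        return aggregate(self.ensemble, ddof=ddof)


def _look_at(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation for a camera at ``position`` whose optical
    axis points at ``target`` (rows of R are the camera axes)."""
    z = target - position
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    if abs(z @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def make_rig(
    n_views: int = 3,
    radius: float = 5.0,
    focal: float = 300.0,
    distortion_level: float = 0.0,
    height: float = 0.8,
    image_size: tuple[int, int] = (640, 480),
) -> CameraRig:
    """Cameras evenly spaced on a circle, all looking at the origin.

    ``distortion_level`` scales a fixed set of radial/tangential
    coefficients; 0 gives an exactly distortion-free rig.  A large
    ``radius`` together with a large ``focal`` yields a narrow-field,
    near-affine imaging regime.
    """
    from scipy.spatial.transform import Rotation

    if n_views < 2:
        raise ValueError("a rig needs at least two views")
    cams = []
    base_dist = np.array([-0.2, 0.05, 0.004, -0.003, 0.01])
    for v in range(n_views):
        ang = 2.0 * np.pi * v / n_views
        pos = np.array([radius * np.cos(ang), radius * np.sin(ang), height])
        R = _look_at(pos, np.zeros(3))
        rvec = Rotation.from_matrix(R).as_rotvec()
        t = -R @ pos
        cams.append(
            CameraModel(
                name=f"cam{v}",
                focal=(focal, focal * 1.02),
                principal=(image_size[0] / 2.0, image_size[1] / 2.0),
                distortion=tuple(distortion_level * base_dist),
                rotation=tuple(rvec),
                translation=tuple(t),
                size=image_size,
            )
        )
    return CameraRig(tuple(cams))


def simulate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate a reproducible scene from its specification."""
    rng = np.random.default_rng(spec.seed)
    V, K, T, M = spec.n_views, spec.n_keypoints, spec.n_frames, spec.n_members
    rig = make_rig(
        n_views=V,
        radius=spec.rig_radius,
        focal=spec.focal,
        distortion_level=spec.distortion_level,
    )
    E = spec.s_true * spec.process_cov_matrix
    L = np.linalg.cholesky(E + 1e-18 * np.eye(3))
    steps = rng.standard_normal((T - 1, 3)) @ L.T
    center = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    offsets = rng.uniform(-spec.constellation_radius, spec.constellation_radius, size=(K, 3))
    truth3d = center[:, None, :] + offsets[None, :, :]  # [T, K, 3]
    truth2d = np.empty((T, V, K, 2))
    for v, cam in enumerate(rig):
        truth2d[:, v] = project(cam, truth3d)
    # per-entry noise scales (heteroscedastic when hetero > 0)
    sigma = np.full((T, V, K), float(spec.sigma_obs))
    if spec.hetero > 0:
        sigma = sigma * np.exp(spec.hetero * rng.standard_normal((T, V, K)))
    coords = truth2d[None] + rng.standard_normal((M, T, V, K, 2)) * sigma[None, ..., None]
    corrupted = []
    for occ in spec.occlusions:
        frames = np.arange(occ.start, occ.stop)
        disp = np.asarray(occ.displacement, dtype=float)
        if occ.member_correlated:
            spread = CONFIDENT_WRONG_SPREAD if occ.spread is None else occ.spread
            wrong = truth2d[frames, occ.view, occ.keypoint] + disp
            coords[:, frames, occ.view, occ.keypoint] = (
                wrong[None] + rng.standard_normal((M, frames.size, 2)) * spread
            )
        else:
            noise_scale = float(np.linalg.norm(disp))
            coords[:, frames, occ.view, occ.keypoint] = (
                truth2d[frames, occ.view, occ.keypoint][None]
                + rng.standard_normal((M, frames.size, 2)) * noise_scale
            )
        corrupted.extend((int(t), occ.view, occ.keypoint) for t in frames)
    ens = EnsemblePredictions(
        coords=coords,
        keypoint_names=[f"kp{k}" for k in range(K)],
        view_names=rig.names,
    )
    return SyntheticScene(
        rig=rig,
        truth3d=truth3d,
        truth2d=truth2d,
        ensemble=ens,
        corrupted=corrupted,
        spec=spec,
    )


def evaluate(
    predictions: np.ndarray,
    scene: SyntheticScene,
    ensemble_std: np.ndarray | None = None,
    std_percentiles: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 90.0),
) -> dict:
    """Score 2D predictions [T, V, K, 2] against the scene's ground truth.

    Returns per-entry pixel errors, triangulated 3D errors, reprojection
    errors, their means, and mean pixel error restricted to entries whose
    ensemble standard deviation exceeds each percentile threshold (the
    difficulty-stratified error sweep).
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != scene.truth2d.shape:
        raise ValueError(
            f"predictions shape {predictions.shape} != truth {scene.truth2d.shape}"
        )
    pixel_error = np.linalg.norm(predictions - scene.truth2d, axis=-1)  # [T, V, K]
    per_view = np.moveaxis(predictions, 1, 0)  # [V, T, K, 2]
    tri = triangulate_multiview(scene.rig, per_view)  # [T, K, 3]
    error3d = np.linalg.norm(tri - scene.truth3d, axis=-1)  # [T, K]
    _, reproj = reprojection_error(scene.rig, per_view, tri)  # [T, K]
    metrics = {
        "pixel_error": pixel_error,
        "mean_pixel_error": float(np.nanmean(pixel_error)),
        "error_3d": error3d,
        "mean_error_3d": float(np.nanmean(error3d)),
        "reprojection_error": reproj,
        "mean_reprojection_error": float(np.nanmean(reproj)),
    }
    if ensemble_std is None:
        obs = scene.observations()
        ensemble_std = np.sqrt(np.nanmean(obs.variance, axis=-1))  # [T, V, K]
    strat = {}
    flat_err = pixel_error.ravel()
    flat_std = np.asarray(ensemble_std, dtype=float).ravel()
    for p in std_percentiles:
        thresh = np.nanpercentile(flat_std, p)
        sel = flat_std >= thresh
        strat[float(p)] = float(np.nanmean(flat_err[sel])) if np.any(sel) else np.nan
    metrics["pixel_error_by_std_percentile"] = strat
    return metrics
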