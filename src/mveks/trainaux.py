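"""Training-side numeric operators for heatmap-based multi-view pose nets.

Pure array functions, no training-framework coupling: Gaussian target
heatmaps, soft argmax with a radius-based confidence, the 2D->3D->2D
reprojection consistency loss, the patch-mask occlusion curriculum, and
geometry-consistent 3D label augmentation.

Heatmaps use the same pixel convention as :mod:`mveks.geometry`
(x = column, y = row, origin top-left).  Heatmap grids live at a reduced
resolution relative to the image; every stack carries an explicit
grid->image scale so the geometric operators can move between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CameraRig, project, triangulate_multiview

__all__ = [
    "HeatmapStack",
    "MaskSchedule",
    "Augment3DParams",
    "spatial_softmax",
    "soft_argmax",
    "heatmap_expectation",
    "gaussian_heatmap",
    "reprojection_loss",
    "mask_fraction",
    "sample_patch_mask",
    "fit_similarity",
    "augment_3d",
]

DEFAULT_TEMPERATURE = 1000.0  # inference-time softmax temperature
DEFAULT_CONFIDENCE_RADIUS = 3.0  # heatmap pixels
DEFAULT_SIGMA = 1.25  # Gaussian label width, heatmap pixels
DEFAULT_DOWNSAMPLE = 4  # heatmap grid at 1/4 image resolution


@dataclass
class HeatmapStack:
    """A stack of per-keypoint heatmaps plus its grid->image transform.

    values : [K, h, w] nonnegative
    scale : image pixels per heatmap pixel (affine grid-to-pixel map
        image_xy = scale * grid_xy)
    """

    values: np.ndarray
    scale: float = float(DEFAULT_DOWNSAMPLE)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be [K, h, w], got {self.values.shape}")


@dataclass(frozen=True)
class MaskSchedule:
    """Patch-mask curriculum: no masking before ``start_iter``, then the
    masked fraction ramps linearly from ``start_frac`` to ``end_frac``
    at ``end_iter`` and stays there."""

    start_iter: int = 700
    start_frac: float = 0.10
    end_iter: int = 5000
    end_frac: float = 0.50

    def __post_init__(self) -> None:
        if not (0 <= self.start_frac <= 1 and 0 <= self.end_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not self.start_iter < self.end_iter:
            raise ValueError("start_iter must precede end_iter")


@dataclass(frozen=True)
class Augment3DParams:
    """3D label augmentation draws: isotropic scale U(scale_low, scale_high)
    about the per-axis median, per-axis shift of U(shift_low, shift_high)
    times that axis's bounding-box width."""

    scale_low: float = 0.8
    scale_high: float = 1.2
    shift_low: float = -0.25
    shift_high: float = 0.25

    def __post_init__(self) -> None:
        if not self.scale_low > 0:
            raise ValueError("scale_low must be positive")


def spatial_softmax(heatmap: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Normalize a heatmap (..., h, w) to a probability map with
    exp(temperature * value) weighting."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    h = np.asarray(heatmap, dtype=float)
    z = temperature * h
    z = z - z.max(axis=(-2, -1), keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=(-2, -1), keepdims=True)


def heatmap_expectation(heatmap: np.ndarray) -> np.ndarray:
    """Spatial expectation of a heatmap treated as an unnormalized density.

    This is the differentiable coordinate estimate used inside the
    reprojection loss: the maps there are already normalized (the network
    head's spatial softmax), so the mean of h / sum(h) recovers the
    center of a Gaussian bump to near machine precision — unlike the
    sharply peaked inference-time softmax, which localizes to the grid.
    Returns (..., 2) as (x, y).
    """
    hmap = np.asarray(heatmap, dtype=float)
    h, w = hmap.shape[-2:]
    total = hmap.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = hmap / total
    x = (p.sum(axis=-2) * np.arange(w)).sum(axis=-1)
    y = (p.sum(axis=-1) * np.arange(h)).sum(axis=-1)
    return np.stack([x, y], axis=-1)


def soft_argmax(
    heatmap: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    confidence_radius: float = DEFAULT_CONFIDENCE_RADIUS,
    upsample: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Subpixel keypoint location by spatial softmax + spatial expectation.

    heatmap : (..., h, w)
    Returns ``(coords (..., 2) as (x, y), confidence (...))`` where the
    confidence is the total softmax mass within ``confidence_radius``
    heatmap pixels of the expectation.  An all-equal map yields the grid
    centroid by symmetry.

    At the default inference temperature (1000) the softmax collapses
    onto the global maximum, so localization is only as fine as the
    grid; ``upsample > 1`` interpolates the map (bicubic) first, giving
    subpixel precision of about 1/(2*upsample) pixels.
    """
    hm = np.asarray(heatmap, dtype=float)
    if upsample > 1:
        from scipy.ndimage import zoom

        factors = (1,) * (hm.ndim - 2) + (upsample, upsample)
        hm = zoom(hm, factors, order=3, grid_mode=True, mode="nearest")
    p = spatial_softmax(hm, temperature)
    h, w = p.shape[-2:]
    ys = np.arange(h, dtype=float)
    xs = np.arange(w, dtype=float)
    x = (p.sum(axis=-2) * xs).sum(axis=-1)
    y = (p.sum(axis=-1) * ys).sum(axis=-1)
    coords = np.stack([x, y], axis=-1)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    d2 = (gx - x[..., None, None]) ** 2 + (gy - y[..., None, None]) ** 2
    r = confidence_radius * upsample
    conf = np.where(d2 <= r**2, p, 0.0).sum(axis=(-2, -1))
    if upsample > 1:
        # grid_mode zoom maps cell centers: x_up = (x + 0.5) * f - 0.5
        coords = (coords + 0.5) / upsample - 0.5
    return coords, conf


def gaussian_heatmap(
    coords: np.ndarray,
    height: int,
    width: int,
    sigma: float = DEFAULT_SIGMA,
    scale: float = float(DEFAULT_DOWNSAMPLE),
) -> HeatmapStack:
    """Isotropic Gaussian bumps centered at grid coordinates [K, 2].

    Keypoints whose center lies far outside the grid produce an
    all-near-zero map; downstream consumers should treat such maps as
    missing (see :func:`reprojection_loss`).  NaN coordinates give an
    all-zero map.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    ys = np.arange(height, dtype=float)
    xs = np.arange(width, dtype=float)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    maps = np.zeros((coords.shape[0], height, width))
    for k, (cx, cy) in enumerate(coords):
        if not (np.isfinite(cx) and np.isfinite(cy)):
            continue
        maps[k] = np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2.0 * sigma**2))
    return HeatmapStack(values=maps, scale=scale)


def _heatmap_valid(stack: HeatmapStack, peak_floor: float = 1e-4) -> np.ndarray:
    """A keypoint map counts as present when it has appreciable mass."""
    return stack.values.max(axis=(-2, -1)) > peak_floor


def reprojection_loss(
    pred_heatmaps: list[HeatmapStack],
    gt_heatmaps: list[HeatmapStack],
    rig: CameraRig,
    validity: np.ndarray | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> float:
    """Multi-view geometric consistency loss.

    Take the spatial expectation of each predicted per-view map (the
    differentiable density-mean estimate, :func:`heatmap_expectation`),
    lift the grid coordinates to image pixels, triangulate across all
    view pairs, reproject the mean 3D point into every view, regenerate
    Gaussian heatmaps on the grid, and score mean squared error against
    the ground-truth maps scaled by the number of heatmap pixels (h*w).
    Averaged over valid keypoints and views; keypoints visible in fewer
    than two views are excluded.
    """
    V = len(rig)
    if len(pred_heatmaps) != V or len(gt_heatmaps) != V:
        raise ValueError("need one heatmap stack per rig view")
    K, h, w = pred_heatmaps[0].values.shape
    coords_px = np.full((V, K, 2), np.nan)
    valid = np.ones((V, K), dtype=bool)
    for v in range(V):
        stack = pred_heatmaps[v]
        coords_px[v] = heatmap_expectation(stack.values) * stack.scale
        valid[v] &= _heatmap_valid(stack)
    if validity is not None:
        valid &= np.asarray(validity, dtype=bool)
    pts3d = triangulate_multiview(rig, np.where(valid[..., None], coords_px, np.nan))
    kp_ok = np.all(np.isfinite(pts3d), axis=-1)
    if not np.any(kp_ok):
        return 0.0
    total = 0.0
    count = 0
    for v in range(V):
        reproj_px = project(rig[v], pts3d)
        reproj_grid = reproj_px / pred_heatmaps[v].scale
        regen = gaussian_heatmap(
            reproj_grid, h, w, sigma=sigma, scale=pred_heatmaps[v].scale
        )
        for k in range(K):
            if not (kp_ok[k] and valid[v, k]):
                continue
            diff = regen.values[k] - gt_heatmaps[v].values[k]
            total += float(np.mean(diff**2)) * (h * w)
            count += 1
    return total / count if count else 0.0


def mask_fraction(schedule: MaskSchedule, iteration: int) -> float:
    """Masked-patch fraction at a training iteration (piecewise linear)."""
    if iteration < 0:
        raise ValueError("iteration must be nonnegative")
    if iteration < schedule.start_iter:
        return 0.0
    if iteration >= schedule.end_iter:
        return schedule.end_frac
    span = schedule.end_iter - schedule.start_iter
    frac = (iteration - schedule.start_iter) / span
    return schedule.start_frac + frac * (schedule.end_frac - schedule.start_frac)


def sample_patch_mask(
    grid_h: int,
    grid_w: int,
    fraction: float,
    rng: np.random.Generator,
    max_block: int = 4,
) -> np.ndarray:
    """Sample a contiguous-patch occlusion mask on a patch grid.

    Rectangular blocks (side lengths uniform on 1..max_block) are placed
    at random until at least ``fraction`` of the grid is masked; the
    realized fraction overshoots by at most one block.  Returns a boolean
    [grid_h, grid_w] array (True = masked).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    mask = np.zeros((grid_h, grid_w), dtype=bool)
    if fraction == 0.0:
        return mask
    target = fraction * grid_h * grid_w
    while mask.sum() < target:
        bh = int(rng.integers(1, max_block + 1))
        bw = int(rng.integers(1, max_block + 1))
        r = int(rng.integers(0, max(grid_h - bh + 1, 1)))
        c = int(rng.integers(0, max(grid_w - bw + 1, 1)))
        mask[r : r + bh, c : c + bw] = True
    return mask


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 4-DOF similarity (scale-rotation-translation) from
    2D point sets src -> dst.  Returns the 2x3 matrix [sR | t].

    Closed form: parameterize [[a, -b, tx], [b, a, ty]] and solve the
    linear least-squares system.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    ok = np.all(np.isfinite(src), axis=1) & np.all(np.isfinite(dst), axis=1)
    src, dst = src[ok], dst[ok]
    if src.shape[0] < 2:
        raise ValueError("need at least two finite point pairs")
    n = src.shape[0]
    A = np.zeros((2 * n, 4))
    b = np.empty(2 * n)
    A[0::2, 0] = src[:, 0]
    A[0::2, 1] = -src[:, 1]
    A[0::2, 2] = 1.0
    A[1::2, 0] = src[:, 1]
    A[1::2, 1] = src[:, 0]
    A[1::2, 3] = 1.0
    b[0::2] = dst[:, 0]
    b[1::2] = dst[:, 1]
    a, bb, tx, ty = np.linalg.lstsq(A, b, rcond=None)[0]
    return np.array([[a, -bb, tx], [bb, a, ty]])


def augment_3d(
    labels2d: np.ndarray,
    rig: CameraRig,
    params: Augment3DParams = Augment3DParams(),
    rng: np.random.Generator | None = None,
    scale: float | None = None,
    shift: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Geometry-consistent 3D augmentation of multi-view 2D labels.

    labels2d : [V, K, 2] pixel labels (NaN = missing).
    The labels are triangulated, scaled by one scalar draw about the
    per-axis median, translated per axis by a draw times that axis's
    bounding-box width, and reprojected into every view.  ``scale`` and
    ``shift`` override the random draws (used in tests).

    Returns ``(augmented labels2d [V, K, 2], per-view 2x3 similarity
    transforms fitted original -> augmented, augmented 3D points [K, 3])``.
    Untriangulable keypoints pass through unchanged (NaN in the 3D output).
    """
    labels2d = np.asarray(labels2d, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    pts3d = triangulate_multiview(rig, labels2d)
    ok = np.all(np.isfinite(pts3d), axis=-1)
    if scale is None:
        scale = float(rng.uniform(params.scale_low, params.scale_high))
    if shift is None:
        widths = np.nanmax(pts3d[ok], axis=0) - np.nanmin(pts3d[ok], axis=0) if np.any(ok) else np.zeros(3)
        shift = rng.uniform(params.shift_low, params.shift_high, size=3) * widths
    shift = np.asarray(shift, dtype=float)
    med = np.nanmedian(pts3d[ok], axis=0) if np.any(ok) else np.zeros(3)
    aug3d = np.where(ok[:, None], (pts3d - med) * scale + med + shift, np.nan)
    out2d = labels2d.copy()
    transforms = []
    for v, cam in enumerate(rig):
        reproj = project(cam, aug3d)
        out2d[v] = np.where(ok[:, None], reproj, labels2d[v])
        try:
            transforms.append(fit_similarity(labels2d[v][ok], reproj[ok]))
        except (ValueError, np.linalg.LinAlgError):
            transforms.append(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
    return out2d, transforms, aug3d
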