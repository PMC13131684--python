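"""Uncertainty-guided pseudo-label frame selection.

Two stages: (1) a quality filter keeps the frames with the lowest
worst-case posterior predictive variance (max over keypoints, views and
coordinates); (2) a diversity filter clusters the surviving frames in 3D
pose space (triangulated when calibration is available, PCA scores
otherwise) with k-means and keeps the frame nearest each centroid.  The
selected frames are exported as label tables in the standard prediction
CSV dialect, using the smoothed 2D posterior means as coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .geometry import CameraRig, triangulate_multiview

logger = logging.getLogger(__name__)

__all__ = [
    "FrameQuality",
    "SelectionResult",
    "frame_qualities",
    "quality_filter",
    "diversity_select",
    "export_pseudolabels",
]

DEFAULT_KEEP_FRACTION = 0.6
DEFAULT_K = 3000


@dataclass(frozen=True)
class FrameQuality:
    """Worst-case predictive variance for one frame (pixels^2)."""

    frame: int
    sigma2_max: float


@dataclass
class SelectionResult:
    kept_after_quality: np.ndarray  # frame indices surviving stage 1
    selected: np.ndarray  # final frame indices, sorted
    cluster_ids: np.ndarray  # cluster id per selected frame
    pose_space: np.ndarray  # pose vector per kept frame
    imputed: list = field(default_factory=list)  # (frame, keypoint) filled by centroid


def frame_qualities(predictive_variance: np.ndarray) -> list[FrameQuality]:
    """Per-frame sigma^2_max from predictive variances [T, V, K, 2]
    (max over views, keypoints and both coordinates)."""
    pv = np.asarray(predictive_variance, dtype=float)
    sig = np.nanmax(pv.reshape(pv.shape[0], -1), axis=1)
    return [FrameQuality(i, float(s)) for i, s in enumerate(sig)]


def quality_filter(
    qualities: list[FrameQuality], keep_fraction: float = DEFAULT_KEEP_FRACTION
) -> np.ndarray:
    """Keep the floor(keep_fraction * N) frames with the lowest
    sigma^2_max; ties broken by frame index (earlier first)."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if not qualities:
        return np.array([], dtype=int)
    n_keep = int(np.floor(keep_fraction * len(qualities)))
    n_keep = max(n_keep, 1)
    order = sorted(qualities, key=lambda q: (q.sigma2_max, q.frame))
    kept = sorted(q.frame for q in order[:n_keep])
    return np.array(kept, dtype=int)


def _pose_vectors(
    coords: np.ndarray,
    frames: np.ndarray,
    rig: CameraRig | None,
    latent_dim: int = 3,
) -> tuple[np.ndarray, list]:
    """Pose vector per frame: concatenated triangulated 3D keypoints when a
    rig is given, else per-keypoint PCA scores of the stacked 2D coords."""
    T, V, K, _ = coords.shape
    imputed: list = []
    if rig is not None:
        sub = coords[frames]  # [n, V, K, 2]
        per_view = np.moveaxis(sub, 1, 0)  # [V, n, K, 2]
        pts = triangulate_multiview(rig, per_view)  # [n, K, 3]
        for i in range(pts.shape[0]):
            bad = ~np.all(np.isfinite(pts[i]), axis=-1)
            if np.all(bad):
                pts[i] = 0.0
                imputed.extend((int(frames[i]), int(k)) for k in range(K))
                continue
            if np.any(bad):
                centroid = np.nanmean(pts[i][~bad], axis=0)
                pts[i][bad] = centroid
                imputed.extend((int(frames[i]), int(k)) for k in np.nonzero(bad)[0])
        return pts.reshape(pts.shape[0], -1), imputed
    # no calibration: PCA projection of stacked per-frame observations
    flat = coords.reshape(T, -1)
    col_mean = np.nanmean(flat, axis=0)
    flat = np.where(np.isfinite(flat), flat, col_mean)
    d = min(3 * K, latent_dim * K, flat.shape[1])
    scores = PCA(n_components=d).fit_transform(flat)
    return scores[frames], imputed


def diversity_select(
    kept_frames: np.ndarray,
    coords: np.ndarray,
    rig: CameraRig | None = None,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
) -> SelectionResult:
    """Cluster kept frames in pose space and keep one frame per cluster.

    coords : smoothed 2D predictions [T, V, K, 2].
    k is lowered (logged) when it exceeds the number of kept frames.
    Within each k-means cluster the frame with the smallest Euclidean
    distance to the centroid is selected (ties: lowest frame index).
    """
    kept_frames = np.asarray(kept_frames, dtype=int)
    if kept_frames.size == 0:
        raise ValueError("no frames passed the quality filter")
    poses, imputed = _pose_vectors(np.asarray(coords, dtype=float), kept_frames, rig)
    k_eff = int(k)
    if k_eff > kept_frames.size:
        logger.info("k=%d exceeds %d kept frames; lowering", k, kept_frames.size)
        k_eff = kept_frames.size
    km = KMeans(n_clusters=k_eff, n_init=n_init, random_state=seed)
    labels = km.fit_predict(poses)
    selected = []
    cluster_ids = []
    for c in range(k_eff):
        members = np.nonzero(labels == c)[0]
        if members.size == 0:
            continue
        dist = np.linalg.norm(poses[members] - km.cluster_centers_[c], axis=1)
        best = members[np.lexsort((kept_frames[members], dist))[0]]
        selected.append(int(kept_frames[best]))
        cluster_ids.append(c)
    order = np.argsort(selected)
    return SelectionResult(
        kept_after_quality=kept_frames,
        selected=np.asarray(selected, dtype=int)[order],
        cluster_ids=np.asarray(cluster_ids, dtype=int)[order],
        pose_space=poses,
        imputed=imputed,
    )


def export_pseudolabels(
    selection: SelectionResult,
    coords: np.ndarray,
    out_dir,
    view_names: list[str],
    keypoint_names: list[str],
    scorer: str = "mveks",
) -> list:
    """Write per-view label CSVs for the selected frames.

    coords : smoothed predictions [T, V, K, 2]; exported coordinates are
    these posterior means, restricted to the selected frame rows.
    Returns the list of written paths.
    """
    from . import io as _io

    coords = np.asarray(coords, dtype=float)
    if selection.selected.size == 0:
        raise ValueError("selection is empty")
    if selection.selected.max() >= coords.shape[0]:
        raise IndexError(
            f"selected frame {int(selection.selected.max())} outside prediction "
            f"range [0, {coords.shape[0]})"
        )
    return _io.write_labels(
        out_dir,
        coords[selection.selected],
        frames=selection.selected,
        view_names=view_names,
        keypoint_names=keypoint_names,
        scorer=scorer,
    )
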