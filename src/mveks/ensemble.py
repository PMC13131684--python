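"""Ensemble aggregation: median observations and ensemble variances.

An ensemble of M independently trained pose networks predicts every
(frame, view, keypoint) coordinate; the smoother consumes the per-coordinate
median across members as its observation and the per-coordinate variance
across members as its (diagonal) observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnsemblePredictions", "MultiviewObservations", "aggregate"]


@dataclass
class EnsemblePredictions:
    """Raw per-member predictions.

    coords : array [M, T, V, K, 2], pixels (NaN = missing prediction)
    likelihood : optional array [M, T, V, K] in [0, 1]
    keypoint_names, view_names : optional labels carried through I/O
    """

    coords: np.ndarray
    likelihood: np.ndarray | None = None
    keypoint_names: list[str] | None = None
    view_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 5 or self.coords.shape[-1] != 2:
            raise ValueError(f"coords must be [M, T, V, K, 2], got {self.coords.shape}")
        if self.likelihood is not None:
            self.likelihood = np.asarray(self.likelihood, dtype=float)
            if self.likelihood.shape != self.coords.shape[:-1]:
                raise ValueError("likelihood shape must match coords[..., 0]")

    @property
    def n_members(self) -> int:
        return self.coords.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        """(M, T, V, K)"""
        return self.coords.shape[:-1]


@dataclass
class MultiviewObservations:
    """Aggregated smoother input: x_t and the diagonal of D_t.

    coords : array [T, V, K, 2], pixels (per-coordinate ensemble median)
    variance : array [T, V, K, 2], pixels^2 (per-coordinate ensemble variance)
    validity : boolean [T, V, K]; invalid entries are excluded downstream
    """

    coords: np.ndarray
    variance: np.ndarray
    validity: np.ndarray | None = None
    keypoint_names: list[str] | None = None
    view_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.coords.shape != self.variance.shape:
            raise ValueError("coords and variance shapes differ")
        if self.coords.ndim != 4 or self.coords.shape[-1] != 2:
            raise ValueError(f"coords must be [T, V, K, 2], got {self.coords.shape}")
        if self.validity is None:
            self.validity = np.all(np.isfinite(self.coords), axis=-1)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
        if np.any(self.variance[np.isfinite(self.variance)] < 0):
            raise ValueError("variance entries must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_views(self) -> int:
        return self.coords.shape[1]

    @property
    def n_keypoints(self) -> int:
        return self.coords.shape[2]

    def stacked(self, keypoint: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (x [T, 2V], var [T, 2V], valid [T, V]) for one keypoint,
        coordinates stacked view-major as (x1, y1, ..., xV, yV)."""
        T, V = self.n_frames, self.n_views
        x = self.coords[:, :, keypoint, :].reshape(T, 2 * V)
        var = self.variance[:, :, keypoint, :].reshape(T, 2 * V)
        valid = self.validity[:, :, keypoint]
        return x, var, valid


def aggregate(preds: EnsemblePredictions, ddof: int = 1) -> MultiviewObservations:
    """Collapse ensemble members to median observations and variances.

    Median and variance are taken per coordinate (x and y separately)
    over the member axis, ignoring NaN members.  Entries with fewer than
    two finite members are marked invalid.  ``ddof=1`` gives the unbiased
    sample variance (default); ``ddof=0`` the population variance.
    """
    if preds.n_members < 2:
        raise ValueError(
            f"ensemble variance needs at least 2 members, got {preds.n_members}"
        )
    coords = preds.coords
    finite = np.all(np.isfinite(coords), axis=-1)  # [M, T, V, K]
    masked = np.where(finite[..., None], coords, np.nan)
    n_finite = finite.sum(axis=0)  # [T, V, K]
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(masked, axis=0)
        variance = np.nanvar(masked, axis=0, ddof=ddof)
    validity = n_finite >= 2
    median[~validity] = np.nan
    variance[~validity] = np.nan
    return MultiviewObservations(
        coords=median,
        variance=variance,
        validity=validity,
        keypoint_names=preds.keypoint_names,
        view_names=preds.view_names,
    )
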