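"""Cross-view inconsistency detection and variance inflation.

When every ensemble member agrees on a wrong prediction in one view, the
ensemble variance is small and the smoother trusts the bad observation.
Multi-view geometry exposes the failure: if the stacked per-view
observations of a keypoint cannot be explained by a single latent
position, at least one view is wrong regardless of ensemble confidence.

The inconsistency score is a per-view Mahalanobis distance in a factor
analysis model with an uninformative latent prior,

    p(x | z) = N(x | W z + mu_x, D),     B = (W' D^-1 W)^-1,

where, for view v, the latent posterior is formed from the *remaining*
views only (leave-one-out), the predicted observation is
x'_v = W_v mu_{z|x_-v} + mu_x,v, its covariance Q_v = D_v + W_v B_-v W_v',
and d_v = sqrt((x_v - x'_v)' Q_v^-1 (x_v - x'_v)) — the multi-dimensional
analogue of a z-score.  Any view with d_v >= 5 has its two diagonal
entries of D multiplied by 10, and the sweep repeats until every view is
below threshold (leave-one-out B makes each inflation strictly shrink
that view's distance, so the sweep terminates for V >= 3).  With exactly
two views the wrong view is unidentifiable, so both views are inflated
together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "InflationReport",
    "loo_predictive",
    "mahalanobis_view",
    "inflate",
    "inflate_observations",
]

DEFAULT_THRESHOLD = 5.0
DEFAULT_FACTOR = 10.0
DEFAULT_MAX_ROUNDS = 25

_D_FLOOR = 1e-10
_RCOND = 1e-12


@dataclass
class FactorModel:
    """Per-frame factor-analysis observation model for one keypoint.

    loading : W, [2V, d]
    offset : mu_x, [2V]
    noise : diagonal of D, [2V], pixels^2 (per-frame ensemble variances)
    """

    loading: np.ndarray
    offset: np.ndarray
    noise: np.ndarray

    def __post_init__(self) -> None:
        self.loading = np.atleast_2d(np.asarray(self.loading, dtype=float))
        self.offset = np.asarray(self.offset, dtype=float).ravel()
        self.noise = np.maximum(np.asarray(self.noise, dtype=float).ravel(), _D_FLOOR)
        n = self.loading.shape[0]
        if n % 2 or self.offset.shape[0] != n or self.noise.shape[0] != n:
            raise ValueError("inconsistent factor model shapes")

    @property
    def n_views(self) -> int:
        return self.loading.shape[0] // 2

    @property
    def latent_dim(self) -> int:
        return self.loading.shape[1]

    def posterior_matrix(self, exclude_view: int | None = None) -> np.ndarray | None:
        """B = (W' D^-1 W)^-1, optionally leaving one view's rows out.

        Returns None when the system is rank-deficient.
        """
        keep = np.ones(2 * self.n_views, dtype=bool)
        if exclude_view is not None:
            keep[2 * exclude_view : 2 * exclude_view + 2] = False
        W = self.loading[keep]
        Dinv = 1.0 / self.noise[keep]
        A = (W.T * Dinv) @ W
        # scale-aware rank check
        s = np.linalg.svd(A, compute_uv=False)
        if s[-1] <= _RCOND * max(s[0], 1.0):
            return None
        return np.linalg.inv(A)


@dataclass
class InflationReport:
    """Record of an inflation run over [T, V, K] entries."""

    inflated: list  # (frame, view, keypoint, n_inflations)
    final_distances: np.ndarray  # [T, V, K]
    unresolved: list = field(default_factory=list)  # entries that hit the cap
    n_keypoints: int = 0

    @property
    def total_inflation_fraction(self) -> np.ndarray:
        """Fraction of (frame, view) entries inflated, per keypoint."""
        T, V, K = self.final_distances.shape
        counts = np.zeros(K)
        for _, _, k, _ in self.inflated:
            counts[k] += 1
        return counts / float(T * V)

    def to_dict(self) -> dict:
        return {
            "inflated": [
                {"frame": int(t), "view": int(v), "keypoint": int(k), "rounds": int(n)}
                for t, v, k, n in self.inflated
            ],
            "unresolved": [
                {"frame": int(t), "view": int(v), "keypoint": int(k)}
                for t, v, k in self.unresolved
            ],
            "total_inflation_fraction": self.total_inflation_fraction.tolist(),
            "max_final_distance": float(np.nanmax(self.final_distances))
            if np.any(np.isfinite(self.final_distances))
            else 0.0,
        }


def loo_predictive(
    x: np.ndarray, model: FactorModel, view: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Leave-one-out posterior predictive for one view.

    Returns ``(x'_v [2], Q_v [2, 2])``: the predicted observation for
    ``view`` given all remaining views (uninformative latent prior) and
    its covariance D_v + W_v B_-v W_v'.  Returns None when the
    leave-one-out system is rank-deficient.
    """
    x = np.asarray(x, dtype=float).ravel()
    B = model.posterior_matrix(exclude_view=view)
    if B is None:
        return None
    keep = np.ones(2 * model.n_views, dtype=bool)
    keep[2 * view : 2 * view + 2] = False
    W_rest = model.loading[keep]
    Dinv_rest = 1.0 / model.noise[keep]
    mu_z = B @ (W_rest.T * Dinv_rest) @ (x[keep] - model.offset[keep])
    Wv = model.loading[2 * view : 2 * view + 2]
    pred = Wv @ mu_z + model.offset[2 * view : 2 * view + 2]
    Q = Wv @ B @ Wv.T
    Q[np.diag_indices(2)] += model.noise[2 * view : 2 * view + 2]
    return pred, 0.5 * (Q + Q.T)


def mahalanobis_view(x: np.ndarray, model: FactorModel, view: int) -> float:
    """Cross-view inconsistency score for one view.

    sqrt((x_v - x'_v)' Q_v^-1 (x_v - x'_v)); 0.0 when the leave-one-out
    system is rank-deficient (the view is then skipped, logged).
    """
    res = loo_predictive(x, model, view)
    if res is None:
        logger.debug("view %d: leave-one-out system rank-deficient, skipped", view)
        return 0.0
    pred, Q = res
    x = np.asarray(x, dtype=float).ravel()
    r = x[2 * view : 2 * view + 2] - pred
    try:
        L = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError:
        logger.debug("view %d: predictive covariance not PD, jittered", view)
        L = np.linalg.cholesky(Q + 1e-8 * np.trace(Q) * np.eye(2))
    y = np.linalg.solve(L, r)
    return float(np.sqrt(y @ y))


def _inflate_one_frame(
    x: np.ndarray,
    loading: np.ndarray,
    offset: np.ndarray,
    noise: np.ndarray,
    threshold: float,
    factor: float,
    max_rounds: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inflation sweep for a single frame/keypoint.

    Returns (new noise [2V], distances [V], rounds per view [V],
    unresolved mask [V]).
    """
    V = loading.shape[0] // 2
    noise = noise.copy()
    rounds = np.zeros(V, dtype=int)
    unresolved = np.zeros(V, dtype=bool)

    def distances() -> np.ndarray:
        m = FactorModel(loading, offset, noise)
        return np.array([mahalanobis_view(x, m, v) for v in range(V)])

    d = distances()
    if V == 2:
        # wrong view unidentifiable with two views: inflate both together
        while np.any(d >= threshold):
            if rounds.max() >= max_rounds:
                unresolved[:] = d >= threshold
                break
            noise *= factor
            rounds += 1
            d = distances()
        return noise, d, rounds, unresolved
    # V >= 3: sweep views in fixed rig order; each offending view is
    # inflated until its own distance falls below threshold (x'_v depends
    # only on the other views, and Q_v grows with D_v, so this inner loop
    # is monotone and terminates).  Sweeps repeat because inflating one
    # view changes the other views' leave-one-out predictions.
    def one_distance(v: int) -> float:
        return mahalanobis_view(x, FactorModel(loading, offset, noise), v)

    while True:
        changed = False
        for v in range(V):
            d_v = one_distance(v)
            while d_v >= threshold and rounds[v] < max_rounds:
                noise[2 * v : 2 * v + 2] *= factor
                rounds[v] += 1
                changed = True
                d_v = one_distance(v)
        if not changed:
            break
    d = distances()
    unresolved |= d >= threshold
    return noise, d, rounds, unresolved


def inflate(
    coords: np.ndarray,
    variance: np.ndarray,
    loading,
    offset,
    threshold: float = DEFAULT_THRESHOLD,
    factor: float = DEFAULT_FACTOR,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
) -> tuple[np.ndarray, InflationReport]:
    """Run the variance-inflation sweep over all frames of one keypoint.

    coords, variance : [T, 2V] stacked observations and their diagonal
        ensemble variances.
    loading, offset : either fixed arrays ([2V, d], [2V]) shared by all
        frames, or callables ``f(t) -> array`` giving the per-frame
        linearization (used in the nonlinear pipeline).

    Returns (inflated variance [T, 2V], report with keypoint axis K=1).
    """
    coords = np.asarray(coords, dtype=float)
    variance = np.maximum(np.asarray(variance, dtype=float), _D_FLOOR)
    T, n = coords.shape
    V = n // 2
    new_var = variance.copy()
    distances = np.zeros((T, V, 1))
    inflated: list = []
    unresolved_list: list = []
    get_W = loading if callable(loading) else (lambda t: loading)
    get_mu = offset if callable(offset) else (lambda t: offset)
    for t in range(T):
        if not np.all(np.isfinite(coords[t])):
            continue
        W_t = np.asarray(get_W(t), dtype=float)
        mu_t = np.asarray(get_mu(t), dtype=float)
        if not (np.all(np.isfinite(W_t)) and np.all(np.isfinite(mu_t))):
            continue
        nv, d, rounds, unres = _inflate_one_frame(
            coords[t], W_t, mu_t, variance[t], threshold, factor, max_rounds
        )
        new_var[t] = nv
        distances[t, :, 0] = d
        for v in range(V):
            if rounds[v] > 0:
                inflated.append((t, v, 0, int(rounds[v])))
            if unres[v]:
                unresolved_list.append((t, v, 0))
    report = InflationReport(
        inflated=inflated,
        final_distances=distances,
        unresolved=unresolved_list,
        n_keypoints=1,
    )
    return new_var, report


def inflate_observations(
    obs,
    models: dict,
    threshold: float = DEFAULT_THRESHOLD,
    factor: float = DEFAULT_FACTOR,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
):
    """Inflate a full :class:`~mveks.ensemble.MultiviewObservations`.

    ``models`` maps keypoint index -> (loading, offset), fixed or
    per-frame callables as in :func:`inflate`.  Returns a new
    observations object plus a combined :class:`InflationReport`.
    """
    from .ensemble import MultiviewObservations

    T, V, K = obs.n_frames, obs.n_views, obs.n_keypoints
    new_variance = obs.variance.copy()
    distances = np.zeros((T, V, K))
    inflated: list = []
    unresolved: list = []
    for k in range(K):
        x, var, valid = obs.stacked(k)
        loading, offset = models[k]
        new_var_k, rep = inflate(
            x, var, loading, offset, threshold, factor, max_rounds
        )
        mask = np.all(np.isfinite(var), axis=1)
        new_variance[mask, :, k, :] = new_var_k[mask].reshape(-1, V, 2)
        distances[:, :, k] = rep.final_distances[:, :, 0]
        inflated.extend((t, v, k, nr) for t, v, _, nr in rep.inflated)
        unresolved.extend((t, v, k) for t, v, _ in rep.unresolved)
    report = InflationReport(
        inflated=inflated,
        final_distances=distances,
        unresolved=unresolved,
        n_keypoints=K,
    )
    new_obs = MultiviewObservations(
        coords=obs.coords.copy(),
        variance=new_variance,
        validity=obs.validity.copy(),
        keypoint_names=obs.keypoint_names,
        view_names=obs.view_names,
    )
    return new_obs, report
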