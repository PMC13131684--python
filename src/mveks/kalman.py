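"""Linear and nonlinear multi-view ensemble Kalman filter-smoothers.

Each keypoint is smoothed independently under the state-space model

    z_t | z_{t-1} ~ N(z_{t-1}, s E)          (random-walk latent dynamics)
    x_t | z_t     ~ N(W z_t + mu_x, D_t)     (linear observation map)

where x_t stacks the (x, y) pixel coordinates of the keypoint across all
V views, D_t is diagonal with the per-coordinate ensemble variances, and
s is a per-keypoint smoothing scalar.  The linear variant learns (W, mu_x)
by PCA on low-ensemble-variance frames and needs no calibration; the
nonlinear variant replaces W z + mu_x by the calibrated camera projections
f_j(z_t) of a 3D world-point state and runs extended Kalman recursions
with analytic Jacobians.

The smoothing scalar s is chosen per keypoint by maximizing the filter's
marginal log-likelihood with Adam on log s (learning rate 0.25), started
from the standard deviation of temporal differences of the PCA
projections, which typically lies near the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ensemble import MultiviewObservations
from .geometry import CameraRig, project, project_jacobian, triangulate_multiview

logger = logging.getLogger(__name__)

__all__ = [
    "LinearObservationModel",
    "DynamicsModel",
    "LatentPosterior",
    "SmootherOutput",
    "init_linear",
    "init_nonlinear",
    "log_likelihood",
    "kalman_smooth",
    "extended_kalman_smooth",
    "optimize_smoothing",
    "smooth_all_keypoints",
]

# variance assigned to invalid/missing observations: effectively removes
# them from the likelihood without resizing any recursion
MISSING_VARIANCE = 1e12
# floor on observation variances (pixels^2); ensemble variance can be
# exactly zero on degenerate data
VAR_FLOOR = 1e-10


@dataclass
class LinearObservationModel:
    """PCA observation map: x = W z + mu_x + noise."""

    loading: np.ndarray  # [2V, d]
    offset: np.ndarray  # [2V]

    def __post_init__(self) -> None:
        self.loading = np.atleast_2d(np.asarray(self.loading, dtype=float))
        self.offset = np.asarray(self.offset, dtype=float).ravel()
        if self.loading.shape[0] != self.offset.shape[0]:
            raise ValueError("loading rows must match offset length")

    @property
    def latent_dim(self) -> int:
        return self.loading.shape[1]


@dataclass
class DynamicsModel:
    """Random-walk dynamics: transition covariance s * E."""

    process_cov: np.ndarray  # E, [d, d] symmetric PSD
    smoothing: float = 1.0  # s > 0

    def __post_init__(self) -> None:
        E = np.atleast_2d(np.asarray(self.process_cov, dtype=float))
        if not np.allclose(E, E.T, atol=1e-10):
            raise ValueError("process covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(E) < -1e-10):
            raise ValueError("process covariance must be PSD")
        self.process_cov = 0.5 * (E + E.T)
        if not self.smoothing > 0:
            raise ValueError("smoothing scalar must be positive")


@dataclass
class LatentPosterior:
    means: np.ndarray  # [T, d]
    covariances: np.ndarray  # [T, d, d]
    log_marginal_likelihood: float


@dataclass
class SmootherOutput:
    """Per-view posterior predictive summaries, in pixel units."""

    means: np.ndarray  # [T, V, 2]
    variances: np.ndarray  # [T, V, 2, 2]

    @property
    def variance_diag(self) -> np.ndarray:
        """[T, V, 2] diagonal (var_x, var_y) of the 2x2 blocks."""
        return np.stack(
            [self.variances[..., 0, 0], self.variances[..., 1, 1]], axis=-1
        )


def _prepare(x, var, valid):
    """Fill missing observations and floor variances.

    x, var: [T, 2V]; valid: [T, V].  Invalid or non-finite entries get
    MISSING_VARIANCE and a placeholder coordinate (their influence on the
    posterior is then negligible).
    """
    x = np.array(x, dtype=float)
    var = np.array(var, dtype=float)
    T, n = x.shape
    V = n // 2
    valid = np.asarray(valid, dtype=bool)
    coord_valid = np.repeat(valid, 2, axis=1) & np.isfinite(x) & np.isfinite(var)
    fill = np.nanmean(np.where(coord_valid, x, np.nan), axis=0)
    fill = np.where(np.isfinite(fill), fill, 0.0)
    x = np.where(coord_valid, x, fill[None, :])
    var = np.where(coord_valid, np.maximum(var, VAR_FLOOR), MISSING_VARIANCE)
    return x, var, coord_valid


def init_linear(
    obs: MultiviewObservations | tuple,
    keypoint: int = 0,
    latent_dim: int = 3,
    low_var_quantile: float = 50.0,
) -> tuple[LinearObservationModel, DynamicsModel]:
    """Initialize the linear model for one keypoint by PCA.

    Frames where every view is valid and whose maximum ensemble variance
    (across views and coordinates) falls below the ``low_var_quantile``-th
    percentile are used to estimate the offset (their mean) and the
    loading (top-``latent_dim`` principal directions scaled by the
    component standard deviations).  E is the covariance of first
    differences of the PCA projections, and the initial smoothing scalar
    is the mean across latent dimensions of their standard deviations.
    """
    if isinstance(obs, MultiviewObservations):
        x, var, valid = obs.stacked(keypoint)
    else:
        x, var, valid = obs
    x, var, coord_valid = _prepare(x, var, valid)
    frame_ok = np.all(coord_valid, axis=1)
    if frame_ok.sum() < 10:
        raise ValueError(
            f"keypoint {keypoint}: only {int(frame_ok.sum())} fully valid frames; "
            "need at least 10 for PCA initialization"
        )
    maxvar = np.where(frame_ok, var.max(axis=1), np.inf)
    thresh = np.percentile(maxvar[frame_ok], low_var_quantile)
    selected = frame_ok & (maxvar <= thresh)
    if selected.sum() <= latent_dim:
        selected = frame_ok
    xs = x[selected]
    mu = xs.mean(axis=0)
    _, svals, vt = np.linalg.svd(xs - mu, full_matrices=False)
    if svals.shape[0] < latent_dim or svals[latent_dim - 1] <= 1e-10 * max(
        svals[0], 1.0
    ):
        raise ValueError(
            f"keypoint {keypoint}: observations have rank < {latent_dim} "
            "after low-variance filtering"
        )
    directions = vt[:latent_dim].T  # [2V, d], orthonormal
    scales = svals[:latent_dim] / np.sqrt(max(xs.shape[0] - 1, 1))
    W = directions * scales
    model = LinearObservationModel(loading=W, offset=mu)
    # projections of all fully valid frames; differences across valid pairs
    z = ((x - mu) @ directions) / scales
    pair_ok = frame_ok[1:] & frame_ok[:-1]
    dz = np.diff(z, axis=0)[pair_ok]
    if dz.shape[0] < 2:
        raise ValueError(f"keypoint {keypoint}: too few consecutive valid frames")
    E = np.atleast_2d(np.cov(dz.T))
    E = 0.5 * (E + E.T) + 1e-12 * np.eye(latent_dim)
    s_init = float(np.mean(dz.std(axis=0)))
    s_init = max(s_init, 1e-6)
    return model, DynamicsModel(process_cov=E, smoothing=s_init)


def _initial_state_linear(x0, var0, model, dyn):
    """GLS estimate of z from the first frame; covariance 10 E."""
    W, mu = model.loading, model.offset
    Dinv = 1.0 / var0
    A = (W.T * Dinv) @ W
    m0 = np.linalg.solve(A, (W.T * Dinv) @ (x0 - mu))
    P0 = 10.0 * dyn.process_cov
    return m0, P0


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def _logdet_solve(S, y):
    """(log det S, S^{-1} y) via Cholesky with jitter fallback."""
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        logger.debug("innovation covariance not PD; adding jitter")
        L = np.linalg.cholesky(S + 1e-8 * np.trace(S) / S.shape[0] * np.eye(S.shape[0]))
    half = np.linalg.solve(L, y)
    sol = np.linalg.solve(L.T, half)
    return 2.0 * np.sum(np.log(np.diag(L))), sol, L


_LOG2PI = float(np.log(2.0 * np.pi))


def _linear_filter(x, var, model, dyn, store: bool):
    """Kalman filter over all frames.  Returns (ll, stored arrays or None)."""
    W, mu = model.loading, model.offset
    d = model.latent_dim
    T, n = x.shape
    Q = dyn.smoothing * dyn.process_cov
    m, P = _initial_state_linear(x[0], var[0], model, dyn)
    ll = 0.0
    if store:
        means_f = np.empty((T, d))
        covs_f = np.empty((T, d, d))
        means_p = np.empty((T, d))
        covs_p = np.empty((T, d, d))
    for t in range(T):
        if t > 0:
            P = P + Q
        m_pred, P_pred = m, P
        resid = x[t] - W @ m_pred - mu
        S = W @ P_pred @ W.T
        S[np.diag_indices(n)] += var[t]
        logdet, Sinv_resid, L = _logdet_solve(_symmetrize(S), resid)
        ll += -0.5 * (n * _LOG2PI + logdet + resid @ Sinv_resid)
        PWt = P_pred @ W.T
        K = np.linalg.solve(L.T, np.linalg.solve(L, PWt.T)).T  # P W' S^{-1}
        m = m_pred + K @ resid
        P = _symmetrize(P_pred - K @ W @ P_pred)
        if store:
            means_p[t], covs_p[t] = m_pred, P_pred
            means_f[t], covs_f[t] = m, P
    if not store:
        return ll, None
    return ll, (means_f, covs_f, means_p, covs_p)


def _rts(means_f, covs_f, means_p, covs_p):
    """RTS smoother for identity transition dynamics."""
    T, d = means_f.shape
    means_s = means_f.copy()
    covs_s = covs_f.copy()
    for t in range(T - 2, -1, -1):
        G = np.linalg.solve(covs_p[t + 1].T, covs_f[t].T).T  # P_f P_pred^{-1}
        means_s[t] = means_f[t] + G @ (means_s[t + 1] - means_p[t + 1])
        covs_s[t] = _symmetrize(
            covs_f[t] + G @ (covs_s[t + 1] - covs_p[t + 1]) @ G.T
        )
    return means_s, covs_s


def kalman_smooth(
    obs,
    model: LinearObservationModel,
    dyn: DynamicsModel,
    keypoint: int = 0,
) -> tuple[LatentPosterior, SmootherOutput]:
    """Forward Kalman filter + RTS smoother for one keypoint.

    ``obs`` is a :class:`MultiviewObservations` (with ``keypoint``
    selecting the track) or a raw ``(x [T, 2V], var [T, 2V], valid [T, V])``
    tuple.  Returns the latent posterior (with the filter's marginal
    log-likelihood) and per-view posterior predictive means/covariances
    W_v Sigma_t W_v' + D_{v,t}.
    """
    if isinstance(obs, MultiviewObservations):
        x, var, valid = obs.stacked(keypoint)
    else:
        x, var, valid = obs
    x, var, _ = _prepare(x, var, valid)
    ll, stored = _linear_filter(x, var, model, dyn, store=True)
    means_s, covs_s = _rts(*stored)
    post = LatentPosterior(means_s, covs_s, ll)
    W, mu = model.loading, model.offset
    T, n = x.shape
    V = n // 2
    y = means_s @ W.T + mu
    pv = np.empty((T, V, 2, 2))
    for v in range(V):
        Wv = W[2 * v : 2 * v + 2]
        pv[:, v] = np.einsum("ij,tjk,lk->til", Wv, covs_s, Wv)
        pv[:, v, 0, 0] += var[:, 2 * v]
        pv[:, v, 1, 1] += var[:, 2 * v + 1]
    out = SmootherOutput(means=y.reshape(T, V, 2), variances=pv)
    return post, out


def log_likelihood(obs, model, dyn, keypoint: int = 0) -> float:
    """Marginal log-likelihood of the observations under the filter."""
    if isinstance(obs, MultiviewObservations):
        x, var, valid = obs.stacked(keypoint)
    else:
        x, var, valid = obs
    x, var, _ = _prepare(x, var, valid)
    ll, _ = _linear_filter(x, var, model, dyn, store=False)
    return ll


def optimize_smoothing(
    obs,
    model: LinearObservationModel | CameraRig,
    dyn: DynamicsModel,
    keypoint: int = 0,
    learning_rate: float = 0.25,
    max_iter: int = 100,
    tol: float = 1e-4,
    nonlinear: bool = False,
) -> tuple[float, float]:
    """Maximize the filter marginal log-likelihood over the smoothing
    scalar s, in log space for positivity.

    Adam with the stated learning rate; gradients by central differences
    of the log-likelihood.  Non-finite evaluations reject the step and
    halve the effective step size.  Returns ``(s_star, ll_star)`` with
    ``ll_star >= ll(s_init)`` (the best evaluated point is returned).

    With ``nonlinear=True``, ``model`` is a :class:`CameraRig` and the
    likelihood comes from the extended filter.
    """
    if isinstance(obs, MultiviewObservations):
        data = obs.stacked(keypoint)
    else:
        data = obs
    x, var, _ = _prepare(*data)

    def ll_of(log_s: float) -> float:
        d = DynamicsModel(dyn.process_cov, float(np.exp(log_s)))
        try:
            if nonlinear:
                ll, _ = _ekf_filter(x, var, model, d, store=False)
            else:
                ll, _ = _linear_filter(x, var, model, d, store=False)
        except np.linalg.LinAlgError:
            return -np.inf
        return ll

    log_s = float(np.log(dyn.smoothing))
    best_log_s = log_s
    best_ll = ll_of(log_s)
    if not np.isfinite(best_ll):
        raise ValueError("log-likelihood non-finite at the initial smoothing value")
    eps = 1e-3
    m_adam, v_adam = 0.0, 0.0
    beta1, beta2 = 0.9, 0.999
    scale = 1.0
    stagnant = 0
    for it in range(1, max_iter + 1):
        f_plus = ll_of(log_s + eps)
        f_minus = ll_of(log_s - eps)
        if not (np.isfinite(f_plus) and np.isfinite(f_minus)):
            logger.warning("non-finite likelihood during search; halving step")
            scale *= 0.5
            log_s = best_log_s
            continue
        improved = False
        for cand_ls, cand_f in ((log_s + eps, f_plus), (log_s - eps, f_minus)):
            if cand_f > best_ll + 1e-9 * abs(best_ll):
                best_ll, best_log_s = cand_f, cand_ls
                improved = True
        stagnant = 0 if improved else stagnant + 1
        grad = (f_plus - f_minus) / (2.0 * eps)
        m_adam = beta1 * m_adam + (1 - beta1) * grad
        v_adam = beta2 * v_adam + (1 - beta2) * grad * grad
        m_hat = m_adam / (1 - beta1**it)
        v_hat = v_adam / (1 - beta2**it)
        step = scale * learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)
        log_s = log_s + step
        # converged: vanishing step, or no improvement for many iterations
        if abs(step) < tol or stagnant >= 15:
            break
    return float(np.exp(best_log_s)), float(best_ll)


# ---------------------------------------------------------------------------
# nonlinear (extended) filter-smoother


def _rig_arrays(rig: CameraRig):
    """Stacked camera parameters for the vectorized projection below."""
    Rs = np.stack([c.rotation_matrix for c in rig])  # [V, 3, 3]
    ts = np.stack([np.asarray(c.translation, dtype=float) for c in rig])  # [V, 3]
    fs = np.array([c.focal for c in rig])  # [V, 2]
    cs = np.array([c.principal for c in rig])  # [V, 2]
    ds = np.array([c.distortion for c in rig])  # [V, 5]
    return Rs, ts, fs, cs, ds


def _project_all_views(arrs, p: np.ndarray):
    """Project one world point through every camera at once.

    Same math as :func:`mveks.geometry.project` / ``project_jacobian``
    (asserted equal in tests), vectorized over views for the filter's
    inner loop.  Returns (pixels [V, 2], jacobians [V, 2, 3]); NaN rows
    for views the point is behind.
    """
    Rs, ts, fs, cs, ds = arrs
    cam = Rs @ p + ts  # [V, 3]
    Z = cam[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_z = np.where(Z > 0, 1.0 / Z, np.nan)
    x = cam[:, 0] * inv_z
    y = cam[:, 1] * inv_z
    k1, k2, p1, p2, k3 = ds.T
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    pix = np.stack([fs[:, 0] * xd + cs[:, 0], fs[:, 1] * yd + cs[:, 1]], axis=-1)
    V = Rs.shape[0]
    zeros = np.zeros(V)
    J_norm = np.stack(
        [
            np.stack([inv_z, zeros, -x * inv_z], axis=-1),
            np.stack([zeros, inv_z, -y * inv_z], axis=-1),
        ],
        axis=1,
    )  # [V, 2, 3]
    dr = k1 + 2.0 * k2 * r2 + 3.0 * k3 * r2**2
    dxd_dx = radial + 2.0 * x * x * dr + 2.0 * p1 * y + 6.0 * p2 * x
    dxd_dy = 2.0 * x * y * dr + 2.0 * p1 * x + 2.0 * p2 * y
    dyd_dx = 2.0 * x * y * dr + 2.0 * p1 * x + 2.0 * p2 * y
    dyd_dy = radial + 2.0 * y * y * dr + 6.0 * p1 * y + 2.0 * p2 * x
    J_dist = np.stack(
        [
            np.stack([fs[:, 0] * dxd_dx, fs[:, 0] * dxd_dy], axis=-1),
            np.stack([fs[:, 1] * dyd_dx, fs[:, 1] * dyd_dy], axis=-1),
        ],
        axis=1,
    )  # [V, 2, 2] with intrinsics folded in
    J = np.einsum("vij,vjk,vkl->vil", J_dist, J_norm, Rs)
    return pix, J


def init_nonlinear(obs, rig: CameraRig, keypoint: int = 0) -> DynamicsModel:
    """Initialize 3D dynamics for the nonlinear smoother.

    Mirrors the linear initialization in world coordinates: triangulate
    the per-frame observations, take first differences of the 3D track,
    set E to their covariance and the initial smoothing scalar to the
    mean of their per-axis standard deviations.
    """
    if isinstance(obs, MultiviewObservations):
        x, var, valid = obs.stacked(keypoint)
    else:
        x, var, valid = obs
    x, var, _ = _prepare(x, var, valid)
    T, n = x.shape
    V = n // 2
    pts_per_view = np.moveaxis(x.reshape(T, V, 2), 1, 0)  # [V, T, 2]
    usable = var.reshape(T, V, 2).max(axis=2).T < MISSING_VARIANCE  # [V, T]
    tri = triangulate_multiview(rig, np.where(usable[..., None], pts_per_view, np.nan))
    ok = np.all(np.isfinite(tri), axis=1)
    pair_ok = ok[1:] & ok[:-1]
    dz = np.diff(tri, axis=0)[pair_ok]
    if dz.shape[0] < 2:
        raise ValueError(
            f"keypoint {keypoint}: too few triangulable consecutive frames"
        )
    E = np.atleast_2d(np.cov(dz.T))
    E = 0.5 * (E + E.T) + 1e-12 * np.eye(3)
    s_init = max(float(np.mean(dz.std(axis=0))), 1e-6)
    return DynamicsModel(process_cov=E, smoothing=s_init)


def _ekf_filter(x, var, rig: CameraRig, dyn: DynamicsModel, store: bool):
    """Extended Kalman filter with the camera projections as observation map.

    State = 3D world position; the per-frame observation stacks the views
    that are usable (finite prediction, point in front of the camera).
    """
    T, n = x.shape
    V = n // 2
    Q = dyn.smoothing * dyn.process_cov
    # initial state: triangulation of the first frame with >= 2 usable views
    m = None
    for t0 in range(T):
        obs_v = x[t0].reshape(V, 2)
        usable = var[t0].reshape(V, 2).max(axis=1) < MISSING_VARIANCE
        if usable.sum() >= 2:
            pt = triangulate_multiview(rig, np.where(usable[:, None], obs_v, np.nan))
            if np.all(np.isfinite(pt)):
                m = pt
                break
    if m is None:
        raise ValueError("no frame with >= 2 valid views to initialize the 3D state")
    P = 10.0 * dyn.process_cov
    ll = 0.0
    if store:
        means_f = np.empty((T, 3))
        covs_f = np.empty((T, 3, 3))
        means_p = np.empty((T, 3))
        covs_p = np.empty((T, 3, 3))
    arrs = _rig_arrays(rig)
    for t in range(T):
        if t > 0:
            P = P + Q
        m_pred, P_pred = m, P
        preds, jacs = _project_all_views(arrs, m_pred)
        ok = np.all(np.isfinite(preds), axis=-1) & np.all(
            np.isfinite(jacs), axis=(-2, -1)
        )
        if not np.all(ok):
            logger.debug("frame %d: views %s behind camera, dropped", t, np.nonzero(~ok)[0])
        if not np.any(ok):
            m, P = m_pred, P_pred
            if store:
                means_p[t], covs_p[t] = m_pred, P_pred
                means_f[t], covs_f[t] = m, P
            continue
        idx = np.repeat(ok, 2)
        H = jacs[ok].reshape(-1, 3)
        resid = (x[t].reshape(V, 2)[ok] - preds[ok]).ravel()
        S = H @ P_pred @ H.T
        S[np.diag_indices(S.shape[0])] += var[t][idx]
        logdet, Sinv_resid, L = _logdet_solve(_symmetrize(S), resid)
        ll += -0.5 * (S.shape[0] * _LOG2PI + logdet + resid @ Sinv_resid)
        PHt = P_pred @ H.T
        K = np.linalg.solve(L.T, np.linalg.solve(L, PHt.T)).T
        m = m_pred + K @ resid
        # one iterated-update relinearization: redo the update about the
        # posterior mean, which removes the leading-order linearization
        # error of the single-step EKF
        preds2, jacs2 = _project_all_views(arrs, m)
        ok2 = ok & np.all(np.isfinite(preds2), axis=-1)
        if np.array_equal(ok2, ok):
            H = jacs2[ok].reshape(-1, 3)
            resid2 = (x[t].reshape(V, 2)[ok] - preds2[ok]).ravel() - H @ (m_pred - m)
            S = H @ P_pred @ H.T
            S[np.diag_indices(S.shape[0])] += var[t][idx]
            try:
                L = np.linalg.cholesky(_symmetrize(S))
                K = np.linalg.solve(L.T, np.linalg.solve(L, (P_pred @ H.T).T)).T
                m = m_pred + K @ resid2
            except np.linalg.LinAlgError:
                logger.debug("frame %d: relinearized update skipped", t)
        P = _symmetrize(P_pred - K @ H @ P_pred)
        if store:
            means_p[t], covs_p[t] = m_pred, P_pred
            means_f[t], covs_f[t] = m, P
    if not store:
        return ll, None
    return ll, (means_f, covs_f, means_p, covs_p)


def extended_kalman_smooth(
    obs,
    rig: CameraRig,
    dyn: DynamicsModel,
    keypoint: int = 0,
) -> tuple[LatentPosterior, SmootherOutput]:
    """Nonlinear filter-smoother: 3D world-point state, calibrated
    camera projections as the observation map (EKF + RTS).

    Per-view outputs are the reprojections of the smoothed 3D means with
    linearized predictive covariance J_v Sigma_t J_v' + D_{v,t}.
    """
    if isinstance(obs, MultiviewObservations):
        x, var, valid = obs.stacked(keypoint)
    else:
        x, var, valid = obs
    x, var, _ = _prepare(x, var, valid)
    if dyn.process_cov.shape != (3, 3):
        raise ValueError("nonlinear smoothing requires a 3x3 process covariance")
    ll, stored = _ekf_filter(x, var, rig, dyn, store=True)
    means_s, covs_s = _rts(*stored)
    post = LatentPosterior(means_s, covs_s, ll)
    T = x.shape[0]
    V = len(rig)
    y = np.empty((T, V, 2))
    pv = np.empty((T, V, 2, 2))
    for v, cam in enumerate(rig):
        y[:, v] = project(cam, means_s)
        J = project_jacobian(cam, means_s)  # [T, 2, 3]
        pv[:, v] = np.einsum("tij,tjk,tlk->til", J, covs_s, J)
        pv[:, v, 0, 0] += var[:, 2 * v]
        pv[:, v, 1, 1] += var[:, 2 * v + 1]
    return post, SmootherOutput(means=y, variances=pv)


def smooth_all_keypoints(
    obs: MultiviewObservations,
    mode: str = "linear",
    rig: CameraRig | None = None,
    latent_dim: int = 3,
    smoothing: float | str = "auto",
    low_var_quantile: float = 50.0,
) -> dict:
    """Run the per-keypoint smoother over every keypoint independently.

    Returns a dict with per-keypoint lists: ``posteriors``,
    ``outputs``, ``smoothing`` (chosen s), ``log_likelihoods``.
    Keypoints are independent; results do not depend on execution order.
    """
    if mode not in ("linear", "nonlinear"):
        raise ValueError(f"mode must be 'linear' or 'nonlinear', got {mode!r}")
    if mode == "nonlinear" and rig is None:
        raise ValueError(
            "nonlinear smoothing requires camera calibration (rig); "
            "use mode='linear' when no calibration is available"
        )
    posteriors, outputs, s_list, ll_list = [], [], [], []
    for k in range(obs.n_keypoints):
        data = obs.stacked(k)
        if mode == "nonlinear":
            dyn3 = init_nonlinear(data, rig, keypoint=k)
            if isinstance(smoothing, str):
                s_star, _ = optimize_smoothing(data, rig, dyn3, nonlinear=True)
            else:
                s_star = float(smoothing)
            dyn_fit = DynamicsModel(dyn3.process_cov, s_star)
            post, out = extended_kalman_smooth(data, rig, dyn_fit)
        else:
            model, dyn = init_linear(
                data,
                keypoint=k,
                latent_dim=latent_dim,
                low_var_quantile=low_var_quantile,
            )
            if isinstance(smoothing, str):
                s_star, _ = optimize_smoothing(data, model, dyn)
            else:
                s_star = float(smoothing)
            dyn_fit = DynamicsModel(dyn.process_cov, s_star)
            post, out = kalman_smooth(data, model, dyn_fit)
        posteriors.append(post)
        outputs.append(out)
        s_list.append(s_star)
        ll_list.append(post.log_marginal_likelihood)
    return {
        "posteriors": posteriors,
        "outputs": outputs,
        "smoothing": s_list,
        "log_likelihoods": ll_list,
    }
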