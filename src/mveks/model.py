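"""Model/Results interface for the multi-view ensemble Kalman smoother.

:class:`MultiviewEKS` is constructed from aggregated multi-view
observations (optionally with camera calibration) and ``fit()`` returns
an :class:`EKSResults` carrying the smoothed per-view trajectories,
posterior predictive variances, the chosen smoothing scalar and marginal
log-likelihood per keypoint, the variance-inflation report, and a
``summary()`` table.  Frame selection for pseudo-labeling and CSV export
hang off the results object.

Example
-------
>>> from mveks import synthetic, MultiviewEKS
>>> scene = synthetic.simulate_scene(synthetic.SceneSpec(seed=1))
>>> res = MultiviewEKS(scene.observations(), rig=scene.rig, mode="nonlinear").fit()
>>> res.smoothed_means.shape   # [T, V, K, 2]
(200, 3, 2, 2)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import inflation as _inflation
from . import kalman as _kalman
from .ensemble import EnsemblePredictions, MultiviewObservations, aggregate
from .geometry import CameraRig, project, project_jacobian, triangulate_multiview

logger = logging.getLogger(__name__)

__all__ = ["MultiviewEKS", "EKSResults"]


class MultiviewEKS:
    """Multi-view ensemble Kalman smoother for keypoint trajectories.

    Parameters
    ----------
    observations : MultiviewObservations
        Ensemble-aggregated per-frame observations (median + variance).
    rig : CameraRig, optional
        Camera calibration; required for ``mode='nonlinear'``.
    mode : {'linear', 'nonlinear'}
        Linear PCA observation model or calibrated camera projections.
    latent_dim : int
        Latent dimension of the linear model (3 by default; the stacked
        multi-view observations are projections of a 3D point).
    """

    def __init__(
        self,
        observations: MultiviewObservations,
        rig: CameraRig | None = None,
        mode: str = "linear",
        latent_dim: int = 3,
        low_var_quantile: float = 50.0,
    ) -> None:
        if mode not in ("linear", "nonlinear"):
            raise ValueError(f"mode must be 'linear' or 'nonlinear', got {mode!r}")
        if mode == "nonlinear" and rig is None:
            raise ValueError(
                "nonlinear mode requires camera calibration; pass rig= or "
                "use mode='linear'"
            )
        self.observations = observations
        self.rig = rig
        self.mode = mode
        self.latent_dim = int(latent_dim)
        self.low_var_quantile = float(low_var_quantile)

    @classmethod
    def from_ensemble(cls, preds: EnsemblePredictions, ddof: int = 1, **kwargs):
        """Build directly from raw per-member predictions."""
        return cls(aggregate(preds, ddof=ddof), **kwargs)

    @classmethod
    def from_csv_files(cls, paths: dict[str, list], calibration=None, **kwargs):
        """Build from per-view per-member prediction CSVs (and an optional
        TOML calibration file)."""
        from . import io as _io
        from .geometry import read_calibration

        rig = read_calibration(calibration) if calibration is not None else None
        return cls.from_ensemble(_io.read_predictions(paths), rig=rig, **kwargs)

    # -- linearization of the camera model, reused by inflation ---------
    def _nonlinear_linearization(self, keypoint: int):
        """Per-frame (loading, offset) callables: Jacobian linearization of
        the projection about the triangulated observation."""
        obs = self.observations
        x, var, valid = obs.stacked(keypoint)
        T, n = x.shape
        V = n // 2
        pts_per_view = np.moveaxis(x.reshape(T, V, 2), 1, 0)
        ok = np.repeat(valid, 2, axis=1) & np.isfinite(x)
        pts_masked = np.where(np.moveaxis(ok.reshape(T, V, 2), 1, 0), pts_per_view, np.nan)
        tri = triangulate_multiview(self.rig, pts_masked)  # [T, 3]
        W = np.full((T, n, 3), np.nan)
        mu = np.full((T, n), np.nan)
        for v, cam in enumerate(self.rig):
            h = project(cam, tri)  # [T, 2]
            J = project_jacobian(cam, tri)  # [T, 2, 3]
            W[:, 2 * v : 2 * v + 2, :] = J
            mu[:, 2 * v : 2 * v + 2] = h - np.einsum("tij,tj->ti", J, tri)
        return (lambda t: W[t]), (lambda t: mu[t])

    def fit(
        self,
        smoothing: float | str = "auto",
        inflate: bool = True,
        inflate_threshold: float = _inflation.DEFAULT_THRESHOLD,
        inflate_factor: float = _inflation.DEFAULT_FACTOR,
        inflate_max_rounds: int = _inflation.DEFAULT_MAX_ROUNDS,
    ) -> "EKSResults":
        """Fit the smoother to every keypoint independently.

        ``smoothing='auto'`` maximizes the marginal likelihood per
        keypoint; a float fixes s for all keypoints.  ``inflate``
        toggles the cross-view variance-inflation pre-pass.
        """
        obs = self.observations
        T, V, K = obs.n_frames, obs.n_views, obs.n_keypoints
        lin_models: dict[int, tuple] = {}
        factor_models: dict[int, tuple] = {}
        dyns: dict[int, _kalman.DynamicsModel] = {}
        for k in range(K):
            if self.mode == "linear":
                model, dyn = _kalman.init_linear(
                    obs.stacked(k),
                    keypoint=k,
                    latent_dim=self.latent_dim,
                    low_var_quantile=self.low_var_quantile,
                )
                lin_models[k] = (model, dyn)
                factor_models[k] = (model.loading, model.offset)
                dyns[k] = dyn
            else:
                dyns[k] = _kalman.init_nonlinear(obs.stacked(k), self.rig, keypoint=k)
                factor_models[k] = self._nonlinear_linearization(k)
        if inflate:
            work_obs, report = _inflation.inflate_observations(
                obs,
                factor_models,
                threshold=inflate_threshold,
                factor=inflate_factor,
                max_rounds=inflate_max_rounds,
            )
        else:
            work_obs, report = obs, None
        posteriors, outputs, s_list, ll_list = [], [], [], []
        for k in range(K):
            data = work_obs.stacked(k)
            dyn = dyns[k]
            if self.mode == "nonlinear":
                if isinstance(smoothing, str):
                    s_star, _ = _kalman.optimize_smoothing(
                        data, self.rig, dyn, nonlinear=True
                    )
                else:
                    s_star = float(smoothing)
                dyn_fit = _kalman.DynamicsModel(dyn.process_cov, s_star)
                post, out = _kalman.extended_kalman_smooth(data, self.rig, dyn_fit)
            else:
                model = lin_models[k][0]
                if isinstance(smoothing, str):
                    s_star, _ = _kalman.optimize_smoothing(data, model, dyn)
                else:
                    s_star = float(smoothing)
                dyn_fit = _kalman.DynamicsModel(dyn.process_cov, s_star)
                post, out = _kalman.kalman_smooth(data, model, dyn_fit)
            posteriors.append(post)
            outputs.append(out)
            s_list.append(s_star)
            ll_list.append(post.log_marginal_likelihood)
        means = np.stack([o.means for o in outputs], axis=2)  # [T, V, K, 2]
        variances = np.stack([o.variances for o in outputs], axis=2)  # [T,V,K,2,2]
        factor_pv = self._factor_predictive_variance(work_obs, factor_models)
        return EKSResults(
            model=self,
            smoothed_means=means,
            predictive_variances=variances,
            posteriors=posteriors,
            smoothing=np.asarray(s_list),
            log_likelihoods=np.asarray(ll_list),
            inflation_report=report,
            working_observations=work_obs,
            factor_predictive_variance=factor_pv,
        )

    def _factor_predictive_variance(self, obs, factor_models) -> np.ndarray:
        """Leave-one-out predictive variance diagonal [T, V, K, 2] from the
        factor model with the (possibly inflated) ensemble variances —
        the quality signal used for pseudo-label filtering."""
        T, V, K = obs.n_frames, obs.n_views, obs.n_keypoints
        out = np.full((T, V, K, 2), np.nan)
        for k in range(K):
            x, var, valid = obs.stacked(k)
            loading, offset = factor_models[k]
            get_W = loading if callable(loading) else (lambda t: loading)
            get_mu = offset if callable(offset) else (lambda t: offset)
            for t in range(T):
                W_t, mu_t = np.asarray(get_W(t)), np.asarray(get_mu(t))
                if not (
                    np.all(np.isfinite(W_t))
                    and np.all(np.isfinite(mu_t))
                    and np.all(np.isfinite(var[t]))
                ):
                    continue
                fm = _inflation.FactorModel(W_t, mu_t, var[t])
                for v in range(V):
                    res = _inflation.loo_predictive(x[t], fm, v)
                    if res is not None:
                        out[t, v, k] = np.diag(res[1])
        return out


@dataclass
class EKSResults:
    """Fitted smoother output; see :class:`MultiviewEKS`."""

    model: MultiviewEKS
    smoothed_means: np.ndarray  # [T, V, K, 2]
    predictive_variances: np.ndarray  # [T, V, K, 2, 2]
    posteriors: list
    smoothing: np.ndarray  # s per keypoint
    log_likelihoods: np.ndarray
    inflation_report: object | None
    working_observations: MultiviewObservations
    factor_predictive_variance: np.ndarray  # [T, V, K, 2]

    @property
    def predictive_variance_diag(self) -> np.ndarray:
        """[T, V, K, 2] — (var_x, var_y) of the smoother's posterior
        predictive covariance blocks."""
        return np.stack(
            [
                self.predictive_variances[..., 0, 0],
                self.predictive_variances[..., 1, 1],
            ],
            axis=-1,
        )

    def summary(self) -> str:
        obs = self.model.observations
        lines = [
            "Multi-view Ensemble Kalman Smoother",
            "=" * 53,
            f"mode: {self.model.mode:<12} frames: {obs.n_frames}   views: "
            f"{obs.n_views}   keypoints: {obs.n_keypoints}",
            f"inflation: {'on' if self.inflation_report is not None else 'off'}",
            "-" * 53,
            f"{'keypoint':<12}{'s':>12}{'loglik':>15}{'inflated %':>12}",
        ]
        names = obs.keypoint_names or [f"kp{k}" for k in range(obs.n_keypoints)]
        frac = (
            self.inflation_report.total_inflation_fraction
            if self.inflation_report is not None
            else np.zeros(obs.n_keypoints)
        )
        for k, name in enumerate(names):
            lines.append(
                f"{name:<12}{self.smoothing[k]:>12.4g}"
                f"{self.log_likelihoods[k]:>15.2f}{100 * frac[k]:>11.2f}%"
            )
        lines.append("=" * 53)
        return "\n".join(lines)

    def select_frames(
        self,
        keep_fraction: float = 0.6,
        k: int = 3000,
        seed: int = 0,
        variance_source: str = "factor",
    ):
        """Two-stage pseudo-label frame selection on the fitted output.

        ``variance_source='factor'`` ranks frames by the leave-one-out
        factor-model predictive variance (the default quality signal);
        ``'posterior'`` uses the smoother's posterior predictive variance.
        """
        from . import pseudolabel as _pl

        if variance_source == "factor":
            pv = self.factor_predictive_variance
        elif variance_source == "posterior":
            pv = self.predictive_variance_diag
        else:
            raise ValueError("variance_source must be 'factor' or 'posterior'")
        quals = _pl.frame_qualities(pv)
        kept = _pl.quality_filter(quals, keep_fraction)
        return _pl.diversity_select(
            kept, self.smoothed_means, rig=self.model.rig, k=k, seed=seed
        )

    def to_csv(self, out_dir, scorer: str = "mveks"):
        """Write per-view smoothed CSVs (x, y, likelihood, var_x, var_y)."""
        from . import io as _io

        obs = self.model.observations
        views = obs.view_names or [f"view{v}" for v in range(obs.n_views)]
        names = obs.keypoint_names or [f"kp{k}" for k in range(obs.n_keypoints)]
        return _io.write_smoothed(
            out_dir,
            self.smoothed_means,
            self.predictive_variance_diag,
            view_names=views,
            keypoint_names=names,
            scorer=scorer,
        )

    def plot_trace(self, keypoint: int = 0, view: int = 0, coord: int = 0, ax=None):
        """Plot the raw median observation and the smoothed trajectory with
        a +/- 2 sd posterior predictive band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        obs = self.model.observations
        t = np.arange(obs.n_frames)
        raw = obs.coords[:, view, keypoint, coord]
        sm = self.smoothed_means[:, view, keypoint, coord]
        sd = np.sqrt(self.predictive_variance_diag[:, view, keypoint, coord])
        ax.plot(t, raw, ".", ms=2, alpha=0.5, label="ensemble median")
        ax.plot(t, sm, lw=1.5, label="smoothed")
        ax.fill_between(t, sm - 2 * sd, sm + 2 * sd, alpha=0.2, label="±2 sd")
        ax.set_xlabel("frame")
        ax.set_ylabel("xy"[coord] + " (px)")
        ax.legend(fontsize=8)
        return ax
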