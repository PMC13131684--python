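"""Readers/writers for prediction/label CSVs and run configuration.

Prediction tables use the community 3-row-header CSV dialect (rows:
scorer / bodyparts / coords) with a frame-index first column and x, y,
likelihood columns per bodypart; one file per camera, with the ensemble
member index encoded in the filename suffix (``<view>_member<m>.csv``).
Smoothed outputs keep x, y, likelihood and add two documented extras per
bodypart, ``var_x`` and ``var_y`` (posterior predictive variance,
pixels^2); readers that ignore unknown coords columns stay compatible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import EnsemblePredictions

__all__ = [
    "RunConfig",
    "read_prediction_csv",
    "write_prediction_csv",
    "read_predictions",
    "write_predictions",
    "write_smoothed",
    "read_labels",
    "write_labels",
]


def read_prediction_csv(path) -> tuple[np.ndarray, np.ndarray | None, list[str], np.ndarray]:
    """Read one per-camera table.

    Returns ``(coords [T, K, 2], likelihood [T, K] or None,
    keypoint_names, frame_index)``.  Tolerates missing likelihood
    columns and extra coords columns.
    """
    try:
        df = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed 3-row header prediction CSV: {exc}") from exc
    if df.columns.nlevels != 3:
        raise ValueError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    T = df.shape[0]
    coords = np.full((T, len(bodyparts), 2), np.nan)
    likelihood = np.full((T, len(bodyparts)), np.nan)
    has_like = False
    for k, bp in enumerate(bodyparts):
        sub = df.xs(bp, axis=1, level=1)
        cols = sub.columns.get_level_values(-1)
        if "x" not in cols or "y" not in cols:
            raise ValueError(f"{path}: bodypart {bp!r} lacks x/y columns")
        coords[:, k, 0] = sub.xs("x", axis=1, level=-1).to_numpy().ravel()
        coords[:, k, 1] = sub.xs("y", axis=1, level=-1).to_numpy().ravel()
        if "likelihood" in cols:
            has_like = True
            likelihood[:, k] = sub.xs("likelihood", axis=1, level=-1).to_numpy().ravel()
    return (
        coords,
        likelihood if has_like else None,
        bodyparts,
        df.index.to_numpy(),
    )


def _frame_index(frames, T: int):
    return np.arange(T) if frames is None else np.asarray(frames)


def write_prediction_csv(
    path,
    coords: np.ndarray,
    likelihood: np.ndarray | None = None,
    keypoint_names: list[str] | None = None,
    scorer: str = "mveks",
    frames=None,
    extras: dict[str, np.ndarray] | None = None,
) -> None:
    """Write one per-camera table (coords [T, K, 2]).

    ``extras`` maps extra coords-level column names (e.g. ``var_x``) to
    [T, K] arrays appended after x/y/likelihood for each bodypart.
    """
    coords = np.asarray(coords, dtype=float)
    T, K, _ = coords.shape
    if keypoint_names is None:
        keypoint_names = [f"kp{k}" for k in range(K)]
    data = {}
    for k, bp in enumerate(keypoint_names):
        data[(scorer, bp, "x")] = coords[:, k, 0]
        data[(scorer, bp, "y")] = coords[:, k, 1]
        if likelihood is not None:
            data[(scorer, bp, "likelihood")] = np.asarray(likelihood)[:, k]
        for name, arr in (extras or {}).items():
            data[(scorer, bp, name)] = np.asarray(arr)[:, k]
    df = pd.DataFrame(data, index=_frame_index(frames, T))
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["scorer", "bodyparts", "coords"]
    )
    # shortest round-trip float repr keeps read(write(x)) bit-exact
    df.to_csv(path, float_format=lambda v: repr(float(v)))


def read_predictions(paths: dict[str, list]) -> EnsemblePredictions:
    """Assemble an ensemble from per-view, per-member CSV paths.

    ``paths`` maps view name -> ordered list of member files.  The
    keypoint order of the first file is canonical; files with the same
    bodyparts in a different column order are reindexed, files with a
    different bodypart set or frame count raise an error naming them.
    """
    view_names = list(paths)
    n_members = {v: len(ps) for v, ps in paths.items()}
    if len(set(n_members.values())) != 1:
        raise ValueError(f"member counts differ across views: {n_members}")
    M = next(iter(n_members.values()))
    ref_names: list[str] | None = None
    ref_T: int | None = None
    coords_all, like_all = [], []
    any_like = False
    for v in view_names:
        coords_v, like_v = [], []
        for p in paths[v]:
            c, like, names, _ = read_prediction_csv(p)
            if ref_names is None:
                ref_names, ref_T = names, c.shape[0]
            if c.shape[0] != ref_T:
                raise ValueError(
                    f"{p}: {c.shape[0]} frames, expected {ref_T} (from first file)"
                )
            if names != ref_names:
                if sorted(names) != sorted(ref_names):
                    raise ValueError(
                        f"{p}: bodyparts {names} do not match {ref_names}"
                    )
                perm = [names.index(n) for n in ref_names]
                c = c[:, perm]
                like = like[:, perm] if like is not None else None
            coords_v.append(c)
            if like is not None:
                any_like = True
            like_v.append(like)
        coords_all.append(coords_v)
        like_all.append(like_v)
    T, K = ref_T, len(ref_names)
    coords = np.empty((M, T, len(view_names), K, 2))
    likelihood = np.full((M, T, len(view_names), K), np.nan) if any_like else None
    for vi in range(len(view_names)):
        for m in range(M):
            coords[m, :, vi] = coords_all[vi][m]
            if any_like and like_all[vi][m] is not None:
                likelihood[m, :, vi] = like_all[vi][m]
    return EnsemblePredictions(
        coords=coords,
        likelihood=likelihood,
        keypoint_names=ref_names,
        view_names=view_names,
    )


def write_predictions(
    out_dir,
    preds: EnsemblePredictions,
    scorer: str = "mveks",
) -> dict[str, list[Path]]:
    """Write one CSV per (view, member): ``<view>_member<m>.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    M, T, V, K = preds.shape
    views = preds.view_names or [f"view{v}" for v in range(V)]
    names = preds.keypoint_names or [f"kp{k}" for k in range(K)]
    written: dict[str, list[Path]] = {v: [] for v in views}
    for vi, view in enumerate(views):
        for m in range(M):
            path = out_dir / f"{view}_member{m}.csv"
            like = None if preds.likelihood is None else preds.likelihood[m, :, vi]
            write_prediction_csv(path, preds.coords[m, :, vi], like, names, scorer)
            written[view].append(path)
    return written


def write_smoothed(
    out_dir,
    means: np.ndarray,
    variance_diag: np.ndarray,
    view_names: list[str],
    keypoint_names: list[str],
    scorer: str = "mveks",
) -> list[Path]:
    """Write per-view smoothed CSVs: x, y, likelihood, var_x, var_y.

    means, variance_diag : [T, V, K, 2].  The likelihood column holds
    exp(-mean predictive std / 10): a monotone confidence summary in
    (0, 1] for readers that expect one; var_x/var_y carry the actual
    posterior predictive variances (pixels^2).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    std = np.sqrt(np.maximum(variance_diag, 0.0)).mean(axis=-1)  # [T, V, K]
    for vi, view in enumerate(view_names):
        path = out_dir / f"{view}_smoothed.csv"
        write_prediction_csv(
            path,
            means[:, vi],
            likelihood=np.exp(-std[:, vi] / 10.0),
            keypoint_names=keypoint_names,
            scorer=scorer,
            extras={
                "var_x": variance_diag[:, vi, :, 0],
                "var_y": variance_diag[:, vi, :, 1],
            },
        )
        paths.append(path)
    return paths


def write_labels(
    out_dir,
    coords: np.ndarray,
    frames: np.ndarray,
    view_names: list[str],
    keypoint_names: list[str],
    scorer: str = "mveks",
) -> list[Path]:
    """Write per-view label CSVs (x, y only) for selected frames.

    coords : [n_selected, V, K, 2]."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for vi, view in enumerate(view_names):
        path = out_dir / f"{view}_labels.csv"
        write_prediction_csv(
            path, coords[:, vi], None, keypoint_names, scorer, frames=frames
        )
        paths.append(path)
    return paths


def read_labels(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read one label CSV; returns (coords [T, K, 2], names, frames)."""
    coords, _, names, frames = read_prediction_csv(path)
    return coords, names, frames


@dataclass
class RunConfig:
    """Flat run configuration, serializable to/from YAML."""

    mode: str = "linear"
    latent_dim: int = 3
    smoothing: str | float = "auto"
    inflate: bool = True
    inflate_threshold: float = 5.0
    inflate_factor: float = 10.0
    inflate_max_rounds: int = 25
    keep_fraction: float = 0.6
    k: int = 3000
    seed: int = 0
    calibration: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError(f"mode must be 'linear' or 'nonlinear', got {self.mode!r}")
        if isinstance(self.smoothing, str) and self.smoothing != "auto":
            self.smoothing = float(self.smoothing)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
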