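"""Feature selection, holdout evaluation and the full experiment grid.

The experiment crosses three input-feature groups — vegetation indices
(VIs), texture features (TFs) and their combination — with the two growth
indices and the four regressors, trains on a random holdout split (40 of 54
quadrats by default) and reports validation R² and nRMSE for each of the 24
cells.  Features enter a group only when their Pearson correlation with both
growth indices is significant at the configured level (0.01).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feat
from .growth_index import FuzzySystem, build_fuzzy_system, compute_cgis
from .imagery import calibrate
from .models import (
    PSOConfig,
    fit_elm,
    fit_pls,
    fit_pso_elm,
    fit_rf,
)
from .synthetic import SyntheticDataset

FEATURE_GROUPS: tuple[str, ...] = ("vis", "tfs", "vis+tfs")
TARGETS: tuple[str, ...] = ("CGI_ewm", "CGI_fce")
MODELS: tuple[str, ...] = ("pls", "rf", "elm", "pso_elm")


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_report(
    features_df: pd.DataFrame,
    targets_df: pd.DataFrame,
    feature_cols: Sequence[str] | None = None,
    target_cols: Sequence[str] = TARGETS,
) -> pd.DataFrame:
    """Pearson r and p for every (feature, target) pair, with 0.05/0.01 flags."""
    if feature_cols is None:
        feature_cols = [c for c in features_df.columns if c != "quadrat_id"]
    rows = []
    for fc in feature_cols:
        for tc in target_cols:
            r, p = pearson(features_df[fc].to_numpy(), targets_df[tc].to_numpy())
            rows.append(
                {
                    "feature": fc,
                    "target": tc,
                    "r": r,
                    "p": p,
                    "sig_05": p < 0.05,
                    "sig_01": p < 0.01,
                }
            )
    return pd.DataFrame(rows)


def select_features(
    features_df: pd.DataFrame,
    targets_df: pd.DataFrame,
    pool: Sequence[str],
    alpha: float = 0.01,
) -> list[str]:
    """Keep pool features significantly correlated with *both* growth indices.

    The selection is the intersection of the two single-target selections at
    level ``alpha``.  An empty result falls back to the full pool with a
    warning so downstream model fits still run.
    """
    selected = []
    for name in pool:
        x = features_df[name].to_numpy(dtype=float)
        if np.std(x) == 0 or not np.all(np.isfinite(x)):
            continue
        ok = True
        for tc in TARGETS:
            _, p = pearson(x, targets_df[tc].to_numpy())
            if not p < alpha:
                ok = False
                break
        if ok:
            selected.append(name)
    if not selected:
        warnings.warn(
            f"no feature passed alpha={alpha} for both targets; using the full pool",
            stacklevel=2,
        )
        return list(pool)
    return selected


def split(n: int, n_train: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random disjoint train/validation partition of ``range(n)``."""
    if not 0 < n_train < n:
        raise ValueError(f"need 0 < n_train < n, got n_train={n_train}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def r_squared(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must be equal-length with >= 2 values")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in y")
    return 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot


def nrmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root mean square error normalized by the observed mean, in percent."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must be equal-length with >= 2 values")
    if y.mean() == 0:
        raise ValueError("zero mean in y")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)) / y.mean() * 100.0)


@dataclass
class ExperimentConfig:
    """Settings of the full evaluation grid."""

    n_train: int = 40
    alpha: float = 0.01
    split_seed: int = 0
    model_seed: int = 0
    n_hidden: int = 5
    pls_components: int = 3
    rf_trees: int = 100
    rf_min_leaf: int = 5
    pso: PSOConfig = field(default_factory=PSOConfig)
    glcm: feat.GLCMSpec = field(default_factory=feat.GLCMSpec)
    recalibrate_from_dn: bool = True


@dataclass
class EvalReport:
    """Grid results plus the relative improvement of combined features over
    vegetation indices alone, per (target, model)."""

    cells: pd.DataFrame
    improvements: pd.DataFrame
    entropy_weights: np.ndarray
    split_seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "cells": self.cells.to_dict(orient="records"),
                "improvements": self.improvements.to_dict(orient="records"),
                "entropy_weights": np.asarray(self.entropy_weights).tolist(),
                "split_seed": self.split_seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        doc = json.loads(text)
        return cls(
            cells=pd.DataFrame(doc["cells"]),
            improvements=pd.DataFrame(doc["improvements"]),
            entropy_weights=np.asarray(doc["entropy_weights"]),
            split_seed=doc["split_seed"],
        )


def dataset_features(
    dataset: SyntheticDataset, config: ExperimentConfig | None = None
) -> pd.DataFrame:
    """Feature table of a campaign, optionally re-deriving reflectance from
    the raw DN patches through the panel calibration."""
    cfg = config or ExperimentConfig()
    if cfg.recalibrate_from_dn:
        sim = dataset.config
        panel_dn = sim.panel_dn
        patches = [
            calibrate(p, panel_dn, sim.panel_reflectance) for p in dataset.dn_patches
        ]
    else:
        patches = dataset.patches
    return feat.feature_table(patches, cfg.glcm)


def _fit_predict(
    model_name: str,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    cfg: ExperimentConfig,
) -> np.ndarray:
    if model_name == "pls":
        return fit_pls(x_train, y_train, cfg.pls_components).predict(x_val)
    if model_name == "rf":
        return fit_rf(
            x_train, y_train, cfg.rf_trees, cfg.rf_min_leaf, seed=cfg.model_seed
        ).predict(x_val)
    if model_name == "elm":
        return fit_elm(x_train, y_train, cfg.n_hidden, seed=cfg.model_seed).predict(x_val)
    if model_name == "pso_elm":
        return fit_pso_elm(x_train, y_train, cfg.n_hidden, cfg.pso).model.predict(x_val)
    raise ValueError(f"unknown model {model_name!r}")


def group_pools(features_df: pd.DataFrame) -> dict[str, list[str]]:
    """Candidate feature columns of the three input groups."""
    vis = [c for c in feat.VI_NAMES if c in features_df.columns]
    tfs = [c for c in feat.TEXTURE_COLUMNS if c in features_df.columns]
    return {"vis": vis, "tfs": tfs, "vis+tfs": vis + tfs}


def evaluate_tables(
    features_df: pd.DataFrame,
    cgis: pd.DataFrame,
    config: ExperimentConfig | None = None,
    entropy_weights: np.ndarray | None = None,
) -> EvalReport:
    """Run the 3 x 2 x 4 grid on already-computed feature and CGI tables.

    For each feature group and growth index, features are screened by
    double-target Pearson significance, a single random holdout split is
    drawn, each regressor is trained on the training part and scored on the
    validation part with R² and nRMSE.
    """
    cfg = config or ExperimentConfig()
    pools = group_pools(features_df)
    n = len(features_df)
    train_idx, val_idx = split(n, cfg.n_train, cfg.split_seed)

    rows = []
    for group in FEATURE_GROUPS:
        cols = select_features(features_df, cgis, pools[group], cfg.alpha)
        x = features_df[cols].to_numpy(dtype=float)
        for target in TARGETS:
            y = cgis[target].to_numpy(dtype=float)
            for model_name in MODELS:
                try:
                    y_hat = _fit_predict(
                        model_name, x[train_idx], y[train_idx], x[val_idx], cfg
                    )
                except Exception as exc:  # re-raise with grid context
                    raise RuntimeError(
                        f"grid cell (group={group}, target={target}, "
                        f"model={model_name}) failed: {exc}"
                    ) from exc
                rows.append(
                    {
                        "group": group,
                        "target": target,
                        "model": model_name,
                        "n_features": len(cols),
                        "features": ",".join(cols),
                        "r2": r_squared(y[val_idx], y_hat),
                        "nrmse": nrmse(y[val_idx], y_hat),
                        "predictions": list(np.asarray(y_hat, dtype=float)),
                        "observed": list(y[val_idx]),
                    }
                )
    cells = pd.DataFrame(rows)

    improvements = []
    for target in TARGETS:
        for model_name in MODELS:
            sub = cells[(cells.target == target) & (cells.model == model_name)]
            r2_vi = float(sub[sub.group == "vis"].r2.iloc[0])
            r2_both = float(sub[sub.group == "vis+tfs"].r2.iloc[0])
            improvements.append(
                {
                    "target": target,
                    "model": model_name,
                    "r2_vis": r2_vi,
                    "r2_vis_tfs": r2_both,
                    "r2_improvement_pct": (
                        100.0 * (r2_both - r2_vi) / abs(r2_vi) if r2_vi != 0 else np.nan
                    ),
                }
            )
    return EvalReport(
        cells=cells,
        improvements=pd.DataFrame(improvements),
        entropy_weights=(
            np.array([]) if entropy_weights is None else np.asarray(entropy_weights)
        ),
        split_seed=cfg.split_seed,
    )


def run_experiment(
    dataset: SyntheticDataset,
    config: ExperimentConfig | None = None,
    system: FuzzySystem | None = None,
) -> EvalReport:
    """Full pipeline grid on one synthetic campaign: calibrate imagery,
    compute features, build both growth indices, then evaluate the grid."""
    cfg = config or ExperimentConfig()
    system = system or build_fuzzy_system()
    features_df = dataset_features(dataset, cfg)
    cgis, ew = compute_cgis(dataset.ground, system)
    return evaluate_tables(features_df, cgis, cfg, entropy_weights=ew.weights)
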