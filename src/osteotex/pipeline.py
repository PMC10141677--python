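"""Spearman-select → PCA → perceptron age regression with leave-one-out folds.

The modelling surface follows the Model/Results idiom: build a
:class:`TextureAgeModel` from a feature table (samples × texture features
with integer age labels), call :meth:`~TextureAgeModel.fit`, and read the
pooled cross-validated predictions and error metrics off the returned
:class:`LooResults`.

Every fold re-runs the full chain on its training rows only — feature
ranking by absolute Spearman correlation with age (top 15), per-feature
standardization, PCA to 3 components, score standardization and a perceptron
with two hidden layers of 10 rectified-linear units — so the held-out sample
never leaks into selection, centering, scaling, basis or weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neural_network import MLPRegressor


class DegenerateLabelsError(ValueError):
    """Labels are constant on the training rows; ranking is undefined."""


class RankError(ValueError):
    """Training data have fewer non-degenerate directions than components."""


def spearman_select(
    features: pd.DataFrame, ages: np.ndarray, k: int = 15
) -> List[str]:
    """Rank features by |Spearman ρ| against age and return the top ``k``.

    Ties (including constant features, whose ρ is taken as 0) are broken by
    schema order, so the selection is deterministic.
    """
    y = np.asarray(ages, dtype=np.float64)
    if features.shape[0] < 3:
        raise ValueError("Spearman selection needs at least 3 training rows")
    if np.ptp(y) == 0:
        raise DegenerateLabelsError("age labels are constant on the training rows")
    x_ranks = np.apply_along_axis(stats.rankdata, 0, features.to_numpy(dtype=np.float64))
    y_ranks = stats.rankdata(y)
    xc = x_ranks - x_ranks.mean(axis=0)
    yc = y_ranks - y_ranks.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xc * yc[:, None]).sum(axis=0) / denom
    abs_rho = np.abs(np.nan_to_num(rho, nan=0.0))
    order = np.argsort(-abs_rho, kind="stable")  # stable: ties keep schema order
    return [features.columns[i] for i in order[:k]]


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Dict[str, float]:
    """MSE, RMSE, MAE and R² of pooled predictions.

    R² uses the mean of the true labels over all samples as the baseline:
    ``R² = 1 − Σ(y−ŷ)² / Σ(y−ȳ)²``.
    """
    y = np.asarray(y_true, dtype=np.float64)
    yhat = np.asarray(y_pred, dtype=np.float64)
    err = y - yhat
    mse = float((err**2).mean())
    rmse = float(np.sqrt(mse))
    mae = float(np.abs(err).mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float(1.0 - (err**2).sum() / ss_tot) if ss_tot > 0 else float("nan")
    return {"r2": r2, "rmse": rmse, "mse": mse, "mae": mae}


@dataclass
class FoldModel:
    """Everything fitted on one training fold, applicable to held-out rows."""

    selected_features: List[str]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    pca: PCA
    score_std: np.ndarray
    regressor: MLPRegressor
    seed: int
    label_range: Optional[Tuple[float, float]] = None

    @property
    def pca_basis(self) -> np.ndarray:
        return self.pca.components_

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.selected_features].to_numpy(dtype=np.float64)
        z = (x - self.feature_mean) / self.feature_std
        scores = self.pca.transform(z)
        return scores / self.score_std

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predict ages; predictions are clamped to the training fold's
        label range, since ages outside the observed cohort span are
        extrapolations the perceptron cannot support."""
        pred = self.regressor.predict(self.transform(features))
        if self.label_range is not None:
            pred = np.clip(pred, *self.label_range)
        return pred


def fit_regressor(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    hidden_layer_sizes: Tuple[int, int] = (10, 10),
    max_iter: int = 4000,
) -> MLPRegressor:
    """Train the two-hidden-layer perceptron (deterministic given the seed).

    L-BFGS is used as the optimizer: full-batch, so the only randomness is
    the seeded weight initialization, and small problems converge quickly.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regressor inputs")
    if x.shape[0] < 4:
        raise ValueError("perceptron training needs at least 4 samples")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    mlp = MLPRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        solver="lbfgs",
        alpha=1e-4,
        max_iter=max_iter,
        tol=1e-8,
        random_state=int(seed) % (2**31 - 1),
    )
    with warnings.catch_warnings():
        # L-BFGS may stop at the iteration cap instead of the 1e-8 tolerance;
        # on these small problems the fit is already at numerical accuracy
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(x, y)
    return mlp


class TextureAgeModel:
    """Age regression from texture features, evaluated by leave-one-out.

    Parameters
    ----------
    features : DataFrame
        Samples × features, no missing values.
    ages : array-like of int
        Age label per sample (years).
    groups : array-like, optional
        Patient identifier per sample; required for ``group_folds``.
    k_select : int
        Number of features kept by Spearman ranking per fold (default 15).
    n_components : int
        Number of principal components (default 3).
    hidden_layer_sizes : tuple of int
        Perceptron hidden topology (default ``(10, 10)``).
    group_folds : bool
        If True, leave one *patient* out per fold instead of one image.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        ages,
        groups=None,
        *,
        k_select: int = 15,
        n_components: int = 3,
        hidden_layer_sizes: Tuple[int, int] = (10, 10),
        group_folds: bool = False,
    ):
        features = pd.DataFrame(features)
        if features.isna().any().any():
            raise ValueError("feature table contains missing values")
        ages = np.asarray(ages)
        if len(ages) != len(features):
            raise ValueError("label count must equal row count")
        if len(features) < 4:
            raise ValueError("leave-one-out evaluation needs at least 4 samples")
        if group_folds and groups is None:
            raise ValueError("group_folds requires patient groups")
        self.features = features.reset_index(drop=True)
        self.ages = ages.astype(np.int64)
        self.groups = None if groups is None else np.asarray(groups)
        self.k_select = int(k_select)
        self.n_components = int(n_components)
        self.hidden_layer_sizes = tuple(hidden_layer_sizes)
        self.group_folds = bool(group_folds)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        *,
        age_col: str = "age_years",
        group_col: Optional[str] = "patient_id",
        feature_cols: Optional[Sequence[str]] = None,
        **kwargs,
    ) -> "TextureAgeModel":
        """Build a model from a flat table carrying labels and provenance."""
        meta = {age_col, group_col} | {"region_kind", "modality", "source_format"}
        if feature_cols is None:
            feature_cols = [c for c in table.columns if c not in meta]
        groups = table[group_col].to_numpy() if group_col and group_col in table else None
        return cls(table[list(feature_cols)], table[age_col].to_numpy(), groups, **kwargs)

    # -- fold-level fitting --------------------------------------------------

    def fit_fold(self, train_idx: np.ndarray, seed: int) -> FoldModel:
        """Run selection → PCA → perceptron on one training subset."""
        train_idx = np.asarray(train_idx)
        x_train = self.features.iloc[train_idx]
        y_train = self.ages[train_idx].astype(np.float64)
        selected = spearman_select(x_train, y_train, k=self.k_select)
        sub = x_train[selected].to_numpy(dtype=np.float64)
        mean = sub.mean(axis=0)
        std = sub.std(axis=0)
        std[std == 0] = 1.0
        z = (sub - mean) / std
        if np.linalg.matrix_rank(z) < self.n_components:
            raise RankError(
                f"training rows span fewer than {self.n_components} directions"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(z)
        score_std = scores.std(axis=0)
        score_std[score_std == 0] = 1.0
        mlp = fit_regressor(
            scores / score_std, y_train, seed, hidden_layer_sizes=self.hidden_layer_sizes
        )
        return FoldModel(
            selected_features=selected,
            feature_mean=mean,
            feature_std=std,
            pca=pca,
            score_std=score_std,
            regressor=mlp,
            seed=int(seed),
            label_range=(float(y_train.min()), float(y_train.max())),
        )

    def _folds(self) -> List[np.ndarray]:
        n = len(self.features)
        if self.group_folds:
            uniq = pd.unique(self.groups)
            return [np.flatnonzero(self.groups == g) for g in uniq]
        return [np.array([i]) for i in range(n)]

    def fit(self, seed: int = 0) -> "LooResults":
        """Leave-one-out evaluation: one fold per sample (or per patient).

        Each fold gets its own deterministic seed derived from the top-level
        one, so refits are bit-reproducible and independent of the held-out
        content.
        """
        n = len(self.features)
        y_pred = np.full(n, np.nan)
        fold_models: List[FoldModel] = []
        all_idx = np.arange(n)
        for fold_index, test_idx in enumerate(self._folds()):
            train_idx = np.setdiff1d(all_idx, test_idx)
            fold_seed = (int(seed) + 1009 * fold_index) % (2**31 - 1)
            try:
                fm = self.fit_fold(train_idx, fold_seed)
            except Exception as exc:
                raise exc.__class__(f"[fold {fold_index}] {exc}") from exc
            y_pred[test_idx] = fm.predict(self.features.iloc[test_idx])
            fold_models.append(fm)
        return LooResults(
            y_true=self.ages.astype(np.float64),
            y_pred=y_pred,
            groups=self.groups,
            fold_models=fold_models,
            seed=int(seed),
            config=self._config_dict(),
        )

    def _config_dict(self) -> Dict:
        return {
            "k_select": self.k_select,
            "n_components": self.n_components,
            "hidden_layer_sizes": list(self.hidden_layer_sizes),
            "group_folds": self.group_folds,
            "n_samples": len(self.features),
            "n_features": self.features.shape[1],
        }


@dataclass
class LooResults:
    """Pooled leave-one-out predictions plus the four error metrics."""

    y_true: np.ndarray
    y_pred: np.ndarray
    groups: Optional[np.ndarray]
    fold_models: List[FoldModel]
    seed: int
    config: Dict

    def __post_init__(self):
        self.metrics = regression_metrics(self.y_true, self.y_pred)

    @property
    def r2(self) -> float:
        return self.metrics["r2"]

    @property
    def rmse(self) -> float:
        return self.metrics["rmse"]

    @property
    def mse(self) -> float:
        return self.metrics["mse"]

    @property
    def mae(self) -> float:
        return self.metrics["mae"]

    @property
    def config_digest(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        """Per-sample true and predicted ages."""
        frame = pd.DataFrame(
            {"age_true": self.y_true, "age_predicted": self.y_pred}
        )
        if self.groups is not None:
            frame.insert(0, "patient_id", self.groups)
        return frame

    def summary(self) -> str:
        """Plain-text summary table of the cross-validated fit."""
        lines = [
            "Texture age regression — leave-one-out results",
            "=" * 48,
            f"samples: {len(self.y_true):>5d}    folds: {len(self.fold_models)}",
            f"selected features per fold: {self.config['k_select']}",
            f"principal components:       {self.config['n_components']}",
            f"hidden layers:              {tuple(self.config['hidden_layer_sizes'])}",
            f"seed: {self.seed}    config digest: {self.config_digest}",
            "-" * 48,
            f"R2   = {self.r2:8.4f}",
            f"RMSE = {self.rmse:8.4f}  years",
            f"MSE  = {self.mse:8.4f}  years^2",
            f"MAE  = {self.mae:8.4f}  years",
            "=" * 48,
        ]
        return "\n".join(lines)

    def save(self, csv_path, json_path) -> None:
        """Write per-sample predictions (CSV) and metrics/config (JSON)."""
        self.to_frame().to_csv(csv_path, index=False)
        payload = {
            "metrics": self.metrics,
            "seed": self.seed,
            "config": self.config,
            "config_digest": self.config_digest,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")

    def plot_predictions(self, ax=None):
        """True vs predicted ages, samples ordered by increasing true age."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        order = np.argsort(self.y_true, kind="stable")
        ax.plot(self.y_true[order], "o", mfc="none", label="true age")
        ax.plot(self.y_pred[order], ".", label="predicted age")
        ax.set_xlabel("sample (ordered by age)")
        ax.set_ylabel("age [years]")
        ax.legend()
        return ax
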