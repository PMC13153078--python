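"""Train/test partitioning, the four regressors, and R²/RMSE evaluation.

Estimators: multiple linear regression (closed-form least squares),
partial least squares regression (NIPALS), epsilon-insensitive support
vector regression (RBF kernel), and K-nearest-neighbor regression.  SVM
and KNN operate on per-feature z-scored inputs using training-partition
statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cross_decomposition import PLSRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from ricelpn.indices import FeatureTable
from ricelpn.synth import ParameterError

ALGORITHMS = ("MLR", "PLSR", "SVM", "KNN")


class RankDeficiencyError(ValueError):
    """Singular design matrix for ordinary least squares."""


class ContractError(ValueError):
    """Dimension or content mismatch with the fitted model."""


class UndefinedR2Error(ValueError):
    """R² undefined for a constant observation vector."""


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 42
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ParameterError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass
class RegressionModel:
    algorithm: str
    feature_names: list[str]
    params: dict[str, Any]
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    _estimator: Any = None  # backing sklearn estimator for PLSR/SVM/KNN


@dataclass(frozen=True)
class EvalResult:
    r2: float
    rmse: float
    n_test: int


def split_dataset(table: FeatureTable, spec: SplitSpec = SplitSpec()) -> tuple[FeatureTable, FeatureTable]:
    """Seeded uniformly-random partition into train and test tables.

    Executed before feature selection and before augmentation in the
    pipeline, so neither stage can see test rows.  With stratify_by set,
    the permutation-and-round split is applied within each stratum.
    """
    n = len(table.values)
    if n < 5:
        raise ParameterError("need at least 5 samples to split")
    rng = np.random.default_rng(spec.seed)
    ids = np.asarray(table.sample_ids, dtype=object)
    if spec.stratify_by is not None:
        strata = table.values[spec.stratify_by] if spec.stratify_by in table.values else None
        if strata is None:
            raise ParameterError(f"stratify_by column {spec.stratify_by!r} not found")
        train_ids: list = []
        for _, grp in table.values.groupby(strata, sort=True):
            gids = np.asarray(grp.index, dtype=object)
            perm = rng.permutation(len(gids))
            k = round(spec.train_fraction * len(gids))
            train_ids.extend(gids[perm[:k]])
        train_mask = np.isin(ids, train_ids)
    else:
        perm = rng.permutation(n)
        k = round(spec.train_fraction * n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:k]] = True
    return table.subset_rows(ids[train_mask]), table.subset_rows(ids[~train_mask])


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    return mean, np.where(std == 0, 1.0, std)


def fit_model(
    train: FeatureTable,
    algorithm: str = "KNN",
    seed: int = 0,
    k: int = 5,
    n_components: int = 3,
    svm_c: float = 10.0,
    svm_epsilon: float = 0.1,
) -> RegressionModel:
    """Fit one of the four estimators on the training table."""
    algorithm = algorithm.upper()
    if algorithm not in ALGORITHMS:
        raise ParameterError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if train.target is None or len(train.values) == 0:
        raise ContractError("training table must be non-empty and carry a target")
    X = train.values.to_numpy(dtype=float)
    y = train.target.to_numpy(dtype=float)
    names = train.feature_names

    if algorithm == "MLR":
        A = np.hstack([np.ones((X.shape[0], 1)), X])
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            # pivoted QR names the columns beyond the numerical rank
            _, _, piv = linalg.qr(A, pivoting=True, mode="economic")
            dependent = [names[j - 1] if j > 0 else "<intercept>" for j in piv[rank:]]
            raise RankDeficiencyError(f"singular design; dependent columns: {dependent}")
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return RegressionModel(
            algorithm="MLR",
            feature_names=names,
            params={"intercept": float(coef[0]), "coefficients": coef[1:].tolist()},
        )

    if algorithm == "PLSR":
        ncomp = min(n_components, X.shape[1], X.shape[0] - 1)
        est = PLSRegression(n_components=ncomp, scale=True)
        est.fit(X, y)
        return RegressionModel(
            algorithm="PLSR",
            feature_names=names,
            params={"n_components": ncomp, "coefficients": est.coef_.ravel().tolist()},
            _estimator=est,
        )

    mean, std = _zscore_fit(X)
    Xz = (X - mean) / std
    if algorithm == "SVM":
        est = SVR(kernel="rbf", C=svm_c, epsilon=svm_epsilon)
        est.fit(Xz, y)
        params = {"kernel": "rbf", "C": svm_c, "epsilon": svm_epsilon, "n_support": int(est.support_.size)}
    else:  # KNN
        k_eff = min(k, X.shape[0])
        est = KNeighborsRegressor(n_neighbors=k_eff, weights="uniform", metric="euclidean")
        est.fit(Xz, y)
        params = {"k": k_eff}
    return RegressionModel(
        algorithm=algorithm,
        feature_names=names,
        params=params,
        scaler_mean=mean,
        scaler_std=std,
        _estimator=est,
    )


def predict(m: RegressionModel, rows) -> np.ndarray:
    """Predict LPN (% dry mass) for a feature matrix or FeatureTable."""
    if isinstance(rows, FeatureTable):
        X = rows.values[m.feature_names].to_numpy(dtype=float)
    elif isinstance(rows, pd.DataFrame):
        X = rows[m.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(rows, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != len(m.feature_names):
        raise ContractError(f"expected {len(m.feature_names)} features, got {X.shape[1]}")
    if m.algorithm == "MLR":
        return m.params["intercept"] + X @ np.asarray(m.params["coefficients"])
    if m.algorithm == "PLSR":
        return m._estimator.predict(X).ravel()
    Xz = (X - m.scaler_mean) / m.scaler_std
    return np.asarray(m._estimator.predict(Xz), dtype=float).ravel()


def evaluate(pred, obs) -> EvalResult:
    """Coefficient of determination and root mean square error.

    R² = 1 - SS_res/SS_tot on the observed mean; RMSE in target units.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ContractError("pred and obs must be 1-D and equal length")
    if obs.size < 2:
        raise ParameterError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedR2Error("R² undefined for constant observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    return EvalResult(
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(np.mean((obs - pred) ** 2))),
        n_test=int(obs.size),
    )
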