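"""Exact Shapley-value attribution by subset enumeration.

For a model f and feature set M, the attribution of feature i on an
instance x is

    phi_i = sum over S subset of M\\{i} of
            |S|! (|M|-|S|-1)! / |M|!  *  ( v(S u {i}) - v(S) )

with the interventional (marginal) value function: v(S) is the mean of
f over hybrid rows that take the instance's values on S and a background
row's values elsewhere, averaged over the background set.  The base
value phi_0 = v(empty set) is the mean background prediction, and
efficiency phi_0 + sum_i phi_i = f(x) holds exactly by construction.

Enumeration over all 2^|M| coalitions is exact and is practical for the
small screened feature sets used here (at most 15 features).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from ricelpn.synth import ParameterError

MAX_EXACT_FEATURES = 15


class CombinatorialLimitError(ValueError):
    """Too many features for exact 2^M enumeration."""


class ContractError(ValueError):
    """Empty background or shape mismatch."""


@dataclass
class ShapExplanation:
    """Base value plus per-sample per-feature Shapley attributions."""

    base_value: float
    values: pd.DataFrame  # samples x features, units of the prediction
    feature_names: list[str]
    background_ids: list

    @property
    def predictions(self) -> pd.Series:
        """Reconstructed model outputs phi_0 + sum_i phi_i per sample."""
        return self.base_value + self.values.sum(axis=1)


def _as_matrix(rows, feature_names=None) -> tuple[np.ndarray, list, list[str]]:
    if isinstance(rows, pd.DataFrame):
        return rows.to_numpy(dtype=float), list(rows.index), list(rows.columns)
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    names = feature_names or [f"x{i + 1}" for i in range(X.shape[1])]
    return X, list(range(X.shape[0])), list(names)


def shapley_values(
    model_predict: Callable[[np.ndarray], np.ndarray],
    background,
    instances,
    feature_names: list[str] | None = None,
) -> ShapExplanation:
    """Exact Shapley attribution of ``model_predict`` on each instance row.

    ``model_predict`` maps an (n, M) matrix to n predictions.  Coalition
    values are computed once per subset on the stacked instance-by-
    background hybrid matrix, then combined with the exact multinomial
    weights.
    """
    bg, bg_ids, bg_names = _as_matrix(background, feature_names)
    X, inst_ids, names = _as_matrix(instances, feature_names or bg_names)
    if bg.shape[0] == 0:
        raise ContractError("background must be non-empty")
    if bg.shape[1] != X.shape[1]:
        raise ContractError("background/instance feature-count mismatch")
    m = X.shape[1]
    if m > MAX_EXACT_FEATURES:
        raise CombinatorialLimitError(
            f"{m} features exceed the exact-enumeration limit {MAX_EXACT_FEATURES}; "
            "screen the feature set first"
        )
    n_inst, n_bg = X.shape[0], bg.shape[0]

    # v[mask][j]: mean prediction over background rows with instance j's
    # values substituted on the features in the mask
    v = np.empty((1 << m, n_inst))
    for mask in range(1 << m):
        hybrid = np.repeat(bg[None, :, :], n_inst, axis=0)  # (inst, bg, m)
        for i in range(m):
            if mask >> i & 1:
                hybrid[:, :, i] = X[:, i][:, None]
        preds = np.asarray(model_predict(hybrid.reshape(-1, m)), dtype=float)
        v[mask] = preds.reshape(n_inst, n_bg).mean(axis=1)

    fact = [factorial(i) for i in range(m + 1)]
    phi = np.zeros((n_inst, m))
    for i in range(m):
        bit = 1 << i
        for mask in range(1 << m):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[m - s - 1] / fact[m]
            phi[:, i] += w * (v[mask | bit] - v[mask])

    # v[0] is identical across instances (pure background); use its first entry
    base = float(v[0, 0])
    values = pd.DataFrame(phi, index=inst_ids, columns=names)
    expl = ShapExplanation(base_value=base, values=values, feature_names=names, background_ids=bg_ids)
    # efficiency is structural; assert it to catch prediction-function bugs
    full = v[(1 << m) - 1]
    resid = np.abs(base + phi.sum(axis=1) - full)
    if resid.size and resid.max() > 1e-8:
        raise AssertionError(f"efficiency violated: max residual {resid.max():.3e}")
    return expl


def rank_features(e: ShapExplanation) -> pd.DataFrame:
    """Features ordered by descending mean |phi|; exact ties by name."""
    if e.values.empty:
        raise ParameterError("empty explanation")
    mean_abs = e.values.abs().mean(axis=0)
    order = sorted(mean_abs.index, key=lambda f: (-mean_abs[f], f))
    return pd.DataFrame(
        {"feature": order, "mean_abs_shap": [float(mean_abs[f]) for f in order]}
    )


def cluster_samples(e: ShapExplanation) -> tuple[list, np.ndarray]:
    """Agglomerative clustering of per-sample Shapley vectors.

    Euclidean distance, average linkage.  Returns (leaf order as sample
    ids, scipy linkage matrix); a single sample yields a single-leaf tree.
    """
    ids = list(e.values.index)
    if len(ids) == 0:
        raise ParameterError("empty explanation")
    if len(ids) == 1:
        return ids, np.empty((0, 4))
    Z = linkage(e.values.to_numpy(dtype=float), method="average", metric="euclidean")
    order = leaves_list(Z)
    return [ids[i] for i in order], Z
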