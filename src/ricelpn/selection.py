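"""Dual-criterion variable screening with collinearity pruning.

Candidates enter by tree-ensemble feature importance (FI > 0.02) or by
absolute Pearson correlation with the target (|r| > 0.75).  The candidate
set is then pruned iteratively: while any pair of survivors correlates at
|r| >= 0.8 with each other, the worst pair is resolved by keeping the
member more correlated with the target; when the two target correlations
are of comparable magnitude (|difference| < comparability_eps), the
higher-FI member is kept; a residual tie falls back to name order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from xgboost import XGBRegressor

from ricelpn.indices import FeatureTable
from ricelpn.synth import ParameterError


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


class ContractError(ValueError):
    """A required input (e.g. the target column) is missing."""


@dataclass(frozen=True)
class SelectionConfig:
    fi_threshold: float = 0.02
    r_threshold: float = 0.75
    collinearity_threshold: float = 0.8
    comparability_eps: float = 0.05
    # ensemble hyperparameters (unpublished; fixed here for reproducibility)
    n_estimators: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("fi_threshold", "r_threshold", "collinearity_threshold", "comparability_eps"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PruneRecord:
    pair: tuple[str, str]
    r_between: float
    rule: str  # "target_correlation" | "feature_importance" | "name_order"
    dropped: str


@dataclass
class SelectionResult:
    selected: list[str]
    fi: pd.Series
    r_target: pd.Series
    pruning_log: list[PruneRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "fi": {k: float(v) for k, v in self.fi.items()},
            "r_target": {k: float(v) for k, v in self.r_target.items()},
            "pruning_log": [
                {"pair": list(rec.pair), "r_between": rec.r_between, "rule": rec.rule, "dropped": rec.dropped}
                for rec in self.pruning_log
            ],
        }


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def fi_scores(table: FeatureTable, cfg: SelectionConfig = SelectionConfig(), seed: int = 0) -> pd.Series:
    """Gain-based importances from a gradient-boosted tree ensemble.

    Nonnegative and normalized to sum to one.  A constant target yields
    all-zero importances with a warning (selection then aborts).
    """
    if table.target is None:
        raise ContractError("feature table has no target")
    if len(table.values) < 10:
        raise ParameterError("need at least 10 samples for importance scoring")
    y = table.target.to_numpy()
    if np.ptp(y) == 0:
        warnings.warn("constant target: importances undefined, returning zeros", stacklevel=2)
        return pd.Series(0.0, index=table.feature_names)
    model = XGBRegressor(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        random_state=seed,
        importance_type="gain",
        n_jobs=1,
        verbosity=0,
    )
    model.fit(table.values.to_numpy(), y)
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=table.feature_names)


def target_correlations(table: FeatureTable) -> pd.Series:
    """Pearson r of each feature with the target; 0 for constant features."""
    if table.target is None:
        raise ContractError("feature table has no target")
    y = table.target.to_numpy()
    out = {}
    for name in table.feature_names:
        x = table.values[name].to_numpy()
        try:
            out[name] = pearson_r(x, y)
        except UndefinedCorrelationError:
            out[name] = 0.0
    return pd.Series(out)


def select_variables(
    table: FeatureTable, cfg: SelectionConfig = SelectionConfig(), seed: int = 0
) -> SelectionResult:
    """Run the full dual-criterion screen with collinearity pruning.

    Must be called on the training partition only to avoid leakage.
    """
    fi = fi_scores(table, cfg, seed=seed)
    if np.ptp(table.target.to_numpy()) == 0:
        warnings.warn("constant target: selection aborted", stacklevel=2)
        return SelectionResult(selected=[], fi=fi, r_target=pd.Series(dtype=float))
    r_target = target_correlations(table)

    candidates = sorted(
        set(fi.index[fi > cfg.fi_threshold]) | set(r_target.index[r_target.abs() > cfg.r_threshold])
    )
    if not candidates:
        warnings.warn("no feature passed either screening threshold", stacklevel=2)
        return SelectionResult(selected=[], fi=fi, r_target=r_target)

    log: list[PruneRecord] = []
    while True:
        sub = table.values[candidates]
        corr = sub.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)  # constant columns give NaN correlations
        worst = float(corr.max())
        if worst < cfg.collinearity_threshold:
            break
        # worst pair: highest |r|; exact ties resolved by name order
        pairs = [
            (candidates[i], candidates[j])
            for i in range(len(candidates))
            for j in range(i + 1, len(candidates))
            if corr[i, j] == worst
        ]
        a, b = sorted(pairs)[0]
        ra, rb = abs(r_target[a]), abs(r_target[b])
        if abs(ra - rb) >= cfg.comparability_eps:
            keep = a if ra > rb else b
            rule = "target_correlation"
        elif fi[a] != fi[b]:
            keep = a if fi[a] > fi[b] else b
            rule = "feature_importance"
        else:
            keep = min(a, b)
            rule = "name_order"
        drop = b if keep == a else a
        log.append(PruneRecord(pair=(a, b), r_between=worst, rule=rule, dropped=drop))
        candidates.remove(drop)
    return SelectionResult(selected=candidates, fi=fi, r_target=r_target, pruning_log=log)
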