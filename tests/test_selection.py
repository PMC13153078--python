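"""Dual-criterion screening: correlations, importances, pruning rules."""

import numpy as np
import pandas as pd
import pytest

from ricelpn.indices import FeatureTable
from ricelpn.selection import (
    SelectionConfig,
    UndefinedCorrelationError,
    fi_scores,
    pearson_r,
    select_variables,
)
from ricelpn.synth import ParameterError


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # direct formula evaluation
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_constant_input_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_errors(self):
        with pytest.raises(ParameterError):
            pearson_r([1, 2], [3, 4])


class TestImportances:
    def test_normalized_and_nonnegative(self, toy_table):
        fi = fi_scores(toy_table, seed=0)
        assert (fi >= 0).all()
        assert fi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_signal_feature_dominates_noise(self):
        # one feature equal to the target among 10 pure-noise columns
        rng = np.random.default_rng(42)
        n = 200
        y = rng.normal(size=n)
        cols = {"signal": y.copy()}
        cols.update({f"noise{i}": rng.normal(size=n) for i in range(10)})
        table = FeatureTable(values=pd.DataFrame(cols), target=pd.Series(y))
        fi = fi_scores(table, seed=0)
        assert fi.idxmax() == "signal"

    def test_constant_target_warns_and_zeroes(self, toy_table):
        table = FeatureTable(values=toy_table.values, target=pd.Series(np.ones(len(toy_table.values))))
        with pytest.warns(UserWarning, match="constant target"):
            fi = fi_scores(table, seed=0)
        assert (fi == 0).all()


def _table(cols: dict, y) -> FeatureTable:
    return FeatureTable(values=pd.DataFrame(cols), target=pd.Series(np.asarray(y, float)))


class TestSelection:
    def test_collinear_pair_resolved_by_target_correlation(self):
        # exact construction on an empirical orthonormal basis:
        # r(f1, y) = 0.9, r(f2, y) = 0.7, r(f1, f2) = 0.9 >= 0.8,
        # so the pair is pruned and f1 (stronger target correlation) survives
        rng = np.random.default_rng(1)
        n = 100
        q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        e1, e2, e3 = (q[:, i] - q[:, i].mean() for i in range(3))
        q2, _ = np.linalg.qr(np.column_stack([e1, e2, e3]))
        e1, e2, e3 = q2.T
        y = e1
        f1 = 0.9 * e1 + np.sqrt(1 - 0.81) * e2
        beta = (0.9 - 0.9 * 0.7) / np.sqrt(0.19)
        gamma = np.sqrt(1 - 0.49 - beta**2)
        f2 = 0.7 * e1 + beta * e2 + gamma * e3
        table = _table({"f1": f1, "f2": f2}, y)
        cfg = SelectionConfig(fi_threshold=0.0, r_threshold=0.0, comparability_eps=0.05)
        res = select_variables(table, cfg, seed=0)
        assert res.selected == ["f1"]
        assert res.pruning_log[0].rule == "target_correlation"
        assert res.pruning_log[0].dropped == "f2"

    def test_comparable_correlations_fall_back_to_importance(self):
        # two near-duplicate features, target correlations within eps;
        # the higher-FI member must be retained
        rng = np.random.default_rng(7)
        n = 200
        base = rng.normal(size=n)
        f1 = base
        f2 = base + 0.01 * rng.normal(size=n)
        extra = rng.normal(size=n)
        y = base + 0.5 * extra
        table = _table({"f1": f1, "f2": f2, "extra": extra}, y)
        cfg = SelectionConfig(fi_threshold=0.0, r_threshold=0.0, comparability_eps=0.05)
        res = select_variables(table, cfg, seed=0)
        fi = res.fi
        rec = next(r for r in res.pruning_log if set(r.pair) == {"f1", "f2"})
        assert rec.rule in ("feature_importance", "name_order")
        kept = ({"f1", "f2"} - {rec.dropped}).pop()
        if rec.rule == "feature_importance":
            assert fi[kept] > fi[rec.dropped]

    def test_no_candidate_passes_thresholds(self, toy_table):
        cfg = SelectionConfig(fi_threshold=1.0, r_threshold=1.0)
        with pytest.warns(UserWarning, match="no feature passed"):
            res = select_variables(toy_table, cfg, seed=0)
        assert res.selected == []

    def test_no_collinear_pair_among_selected(self, toy_table):
        cfg = SelectionConfig(fi_threshold=0.0, r_threshold=0.0)
        res = select_variables(toy_table, cfg, seed=0)
        sub = toy_table.values[res.selected]
        corr = sub.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < cfg.collinearity_threshold

    def test_invariant_to_column_order(self, toy_table):
        cfg = SelectionConfig(fi_threshold=0.0, r_threshold=0.0)
        res_a = select_variables(toy_table, cfg, seed=0)
        shuffled = FeatureTable(
            values=toy_table.values[list(reversed(toy_table.feature_names))],
            target=toy_table.target,
        )
        res_b = select_variables(shuffled, cfg, seed=0)
        assert sorted(res_a.selected) == sorted(res_b.selected)

    def test_raising_thresholds_never_enlarges_candidates(self, toy_table):
        def candidates(fi_th, r_th):
            cfg = SelectionConfig(fi_threshold=fi_th, r_threshold=r_th, collinearity_threshold=1.0)
            return set(select_variables(toy_table, cfg, seed=0).selected)

        loose = candidates(0.0, 0.0)
        tight = candidates(0.1, 0.9)
        assert tight <= loose
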