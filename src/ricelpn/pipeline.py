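"""End-to-end orchestration: simulate → preprocess → features → split →
select → (optionally) augment → fit → evaluate → explain.

The stage order enforces the leakage discipline: the train/test split
happens before feature selection, and selection, WGAN training and model
fitting see training rows only; the test partition is used exactly once,
for final evaluation (and, by default, as the explained instances).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ricelpn import augment as aug
from ricelpn import synth
from ricelpn.explain import ShapExplanation, cluster_samples, rank_features, shapley_values
from ricelpn.indices import FeatureTable, build_feature_table, paper_feature_preset
from ricelpn.models import ALGORITHMS, SplitSpec, evaluate, fit_model, predict, split_dataset
from ricelpn.selection import SelectionConfig, SelectionResult, select_variables
from ricelpn.spectra import gaussian_smooth
from ricelpn.synth import LpnModelParams, ParameterError, SensorModel, SpectrumShapeParams


class ConfigError(ValueError):
    """Invalid run configuration (unknown algorithm, bad nesting)."""


class LeakageError(RuntimeError):
    """A test-partition row reached a training-side stage."""


@dataclass
class RunConfig:
    seed: int = 42
    rates: tuple[float, ...] = synth.DEFAULT_N_RATES
    replicates: int = 5
    subsamples_per_plot: int = 5
    lpn_params: LpnModelParams = field(default_factory=LpnModelParams)
    sensor: SensorModel = field(default_factory=SensorModel)
    shape: SpectrumShapeParams = field(default_factory=SpectrumShapeParams)
    sigma_bands: float = 1.0
    split: SplitSpec | None = None  # defaults to SplitSpec(seed=cfg.seed)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    use_paper_preset: bool = False  # run with the published variable set instead of screening
    augmentation: bool = True
    wgan: aug.WganConfig | None = None  # defaults to WganConfig(seed=cfg.seed)
    n_synthetic: int = 1000
    algorithms: tuple[str, ...] = ALGORITHMS
    knn_k: int = 5
    pls_components: int = 3
    explain_algorithm: str = "KNN"
    explain_partition: str = "test"  # or "train"
    max_background: int = 100
    max_explain_features: int = 10  # cap for exact enumeration; top-|r| features kept
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for algo in self.algorithms:
            if algo.upper() not in ALGORITHMS:
                raise ConfigError(f"unknown algorithm {algo!r}; choose from {ALGORITHMS}")
        if self.explain_algorithm.upper() not in ALGORITHMS:
            raise ConfigError(f"unknown explain_algorithm {self.explain_algorithm!r}")
        if self.explain_partition not in ("test", "train"):
            raise ConfigError("explain_partition must be 'test' or 'train'")
        if self.n_synthetic < 0:
            raise ConfigError("n_synthetic must be nonnegative")


@dataclass
class RunReport:
    metrics: pd.DataFrame  # algorithm × dataset ({original, augmented}) → r2, rmse
    selection: SelectionResult
    selected_features: list[str]
    explanation: ShapExplanation | None
    ranking: pd.DataFrame | None
    leaf_order: list | None
    counts: dict
    seeds: dict
    improvement: dict  # per algorithm: relative/absolute ΔR²
    paths: dict


def _fit_eval(train: FeatureTable, test: FeatureTable, algo: str, cfg: RunConfig, seed: int):
    model = fit_model(
        train, algorithm=algo, seed=seed, k=cfg.knn_k, n_components=cfg.pls_components
    )
    res = evaluate(predict(model, test), test.target.to_numpy())
    return model, res


def run_pipeline(cfg: RunConfig = RunConfig()) -> RunReport:
    """Execute the full analysis under one configuration.

    Returns a RunReport with per-algorithm metrics for the original and
    (if enabled) augmented training data, the selection evidence, and the
    Shapley explanation tables.  With cfg.out_dir set, all intermediate
    tables are written as CSV/JSON under that directory.
    """
    seeds = {
        "master": cfg.seed,
        "synth": cfg.seed,
        "split": cfg.split.seed if cfg.split else cfg.seed,
        "selection": cfg.seed + 1,
        "wgan": cfg.wgan.seed if cfg.wgan else cfg.seed + 2,
        "generate": cfg.seed + 3,
        "background": cfg.seed + 4,
        "fit": cfg.seed + 5,
    }

    # --- simulate and preprocess -------------------------------------------
    samples, spectra = synth.simulate_dataset(
        rates=cfg.rates,
        replicates=cfg.replicates,
        subsamples_per_plot=cfg.subsamples_per_plot,
        params=cfg.lpn_params,
        sensor=cfg.sensor,
        shape=cfg.shape,
        seed=seeds["synth"],
    )
    smoothed = [gaussian_smooth(s, cfg.sigma_bands) for s in spectra]
    table = build_feature_table(
        smoothed,
        lpn=samples["lpn"].to_numpy(),
        sample_ids=list(samples["sample_id"]),
    )

    # --- split, then select on training rows only ---------------------------
    split_spec = cfg.split or SplitSpec(seed=seeds["split"])
    train, test = split_dataset(table, split_spec)
    test_ids = set(test.sample_ids)
    if test_ids & set(train.sample_ids):
        raise LeakageError("train/test partitions overlap")

    selection = select_variables(train, cfg.selection, seed=seeds["selection"])
    if cfg.use_paper_preset:
        selected = paper_feature_preset(table, cfg.sensor.wavelengths)
    else:
        selected = selection.selected
    if not selected:
        raise ParameterError("empty feature selection; nothing to model")

    train_sel = train.subset_features(selected)
    test_sel = test.subset_features(selected)

    # --- models on the original training data -------------------------------
    algorithms = tuple(a.upper() for a in cfg.algorithms)
    rows = []
    models_orig = {}
    for algo in algorithms:
        model, res = _fit_eval(train_sel, test_sel, algo, cfg, seeds["fit"])
        models_orig[algo] = model
        rows.append({"algorithm": algo, "dataset": "original", "r2": res.r2, "rmse": res.rmse})

    # --- WGAN augmentation ---------------------------------------------------
    models_aug = {}
    augmented = None
    if cfg.augmentation:
        train_rows = train_sel.values.copy()
        train_rows["lpn"] = train_sel.target
        if set(train_rows.index) & test_ids:
            raise LeakageError("test rows reached the augmentation stage")
        wgan_cfg = cfg.wgan or aug.WganConfig(seed=seeds["wgan"])
        generator = aug.train_wgan(train_rows, wgan_cfg)
        augmented = aug.augment_dataset(train_rows, generator, cfg.n_synthetic, seed=seeds["generate"])
        aug_table = FeatureTable(
            values=augmented.rows[selected].copy(), target=augmented.rows["lpn"].copy()
        )
        for algo in algorithms:
            model, res = _fit_eval(aug_table, test_sel, algo, cfg, seeds["fit"])
            models_aug[algo] = model
            rows.append({"algorithm": algo, "dataset": "augmented", "r2": res.r2, "rmse": res.rmse})

    metrics = pd.DataFrame(rows, columns=["algorithm", "dataset", "r2", "rmse"])

    improvement = {}
    for algo in algorithms:
        orig = metrics.query("algorithm == @algo and dataset == 'original'")
        augr = metrics.query("algorithm == @algo and dataset == 'augmented'")
        if len(orig) and len(augr):
            r2o, r2a = float(orig["r2"].iloc[0]), float(augr["r2"].iloc[0])
            improvement[algo] = {
                "r2_original": r2o,
                "r2_augmented": r2a,
                "absolute_delta_r2": r2a - r2o,
                "relative_improvement_pct": (r2a - r2o) / r2o * 100 if r2o != 0 else float("nan"),
            }

    # --- Shapley explanation -------------------------------------------------
    explain_algo = cfg.explain_algorithm.upper()
    explanation = ranking = leaf_order = None
    if explain_algo in algorithms:
        model = models_aug.get(explain_algo, models_orig[explain_algo])
        feats = selected
        if len(feats) > cfg.max_explain_features:
            order = sorted(feats, key=lambda f: -abs(selection.r_target.get(f, 0.0)))
            feats = sorted(order[: cfg.max_explain_features], key=feats.index)
        model_f = fit_model(
            (FeatureTable(augmented.rows[feats].copy(), augmented.rows["lpn"].copy())
             if augmented is not None else train_sel.subset_features(feats)),
            algorithm=explain_algo, seed=seeds["fit"], k=cfg.knn_k,
            n_components=cfg.pls_components,
        ) if feats != selected else model
        bg = train_sel.values[feats]
        if len(bg) > cfg.max_background:
            rng = np.random.default_rng(seeds["background"])
            keep = rng.choice(len(bg), size=cfg.max_background, replace=False)
            bg = bg.iloc[np.sort(keep)]
        target_rows = test_sel.values[feats] if cfg.explain_partition == "test" else train_sel.values[feats]
        explanation = shapley_values(lambda X: predict(model_f, X), bg, target_rows, feature_names=feats)
        ranking = rank_features(explanation)
        leaf_order, _ = cluster_samples(explanation)

    counts = {
        "n_plots": len(cfg.rates) * cfg.replicates,
        "n_samples": len(table.values),
        "n_train": len(train.values),
        "n_test": len(test.values),
        "n_band_features": cfg.sensor.n_bands,
        "n_index_features": 20,
        "n_selected": len(selected),
        "n_synthetic": cfg.n_synthetic if cfg.augmentation else 0,
    }

    paths = {}
    if cfg.out_dir is not None:
        paths = _write_outputs(
            Path(cfg.out_dir), cfg, samples, smoothed, table, selection, selected,
            augmented, metrics, improvement, explanation, ranking, leaf_order, seeds, counts,
        )

    return RunReport(
        metrics=metrics,
        selection=selection,
        selected_features=selected,
        explanation=explanation,
        ranking=ranking,
        leaf_order=leaf_order,
        counts=counts,
        seeds=seeds,
        improvement=improvement,
        paths=paths,
    )


def _write_outputs(
    out, cfg, samples, spectra, table, selection, selected, augmented,
    metrics, improvement, explanation, ranking, leaf_order, seeds, counts,
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, writer):
        p = out / name
        p.parent.mkdir(parents=True, exist_ok=True)
        writer(p)
        paths[name] = str(p)

    save("samples.csv", lambda p: samples.to_csv(p, index=False))
    save("spectra.csv", lambda p: synth.spectra_to_frame(samples, spectra).to_csv(p, index=False))
    save("features.csv", lambda p: table.values.assign(lpn=table.target).to_csv(p, index_label="sample_id"))
    save("selection.json", lambda p: p.write_text(json.dumps(selection.to_dict(), indent=2)))
    if augmented is not None:
        save("augmented.csv", lambda p: augmented.rows.assign(origin=augmented.origin).to_csv(p, index_label="row_id"))
    save("metrics.csv", lambda p: metrics.to_csv(p, index=False))
    if explanation is not None:
        save("shap/values.csv", lambda p: explanation.values.assign(base_value=explanation.base_value).to_csv(p, index_label="sample_id"))
        save("shap/ranking.csv", lambda p: ranking.to_csv(p, index=False))
        save("shap/leaf_order.txt", lambda p: p.write_text("\n".join(map(str, leaf_order)) + "\n"))

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": seeds,
        "counts": counts,
        "selected_features": selected,
        "improvement": improvement,
        "outputs": sorted(paths),
    }
    save("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))
    return paths
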