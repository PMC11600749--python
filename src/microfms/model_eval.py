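"""Random-forest benchmarking: weighted F1, MAPE, baselines, orchestration.

The classification metric is the class-size-weighted mean of per-class F1
scores, weighted F1 = sum(w_i * F1_i) / sum(w_i), which is robust to the
class imbalance common in disease labels.  Every real-data score is paired
with a permutation baseline: the same pipeline run on data whose feature
columns were independently permuted, severing the feature-label
association while preserving the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from microfms.augment import augment_training_set, leakage_check
from microfms.feature_select import (
    FeatureSelectionConfig,
    build_predictor_set,
    combine_feature_scores,
    estimate_class_network,
    ml_feature_scores,
    network_degree_difference,
)
from microfms.io_types import RANKS, OTUTable, aggregate_to_level, filter_by_prevalence
from microfms.preprocess import (
    PreprocessSpec,
    ZeroReplacementConfig,
    apply_nm,
    binarize_disease,
    binarize_yield,
    split_train_test,
)

DISEASE_RESPONSES: tuple[str, ...] = ("Scab", "Scabpit", "Scabsuper", "Black_Scurf")
YIELD_RESPONSES: tuple[str, ...] = ("Yield_Meter", "Yield_Plant")
RESPONSES: tuple[str, ...] = YIELD_RESPONSES + DISEASE_RESPONSES


@dataclass(frozen=True)
class RFGrid:
    """Hyperparameter grid for the random-forest classifier.

    The defaults span forest size, tree depth, split granularity and the
    per-split feature subsample; all axes are configurable.
    """

    n_trees: tuple[int, ...] = (100, 500)
    max_depth: tuple[int | None, ...] = (None, 5, 10)
    min_samples_split: tuple[int, ...] = (2, 5)
    max_features: tuple[object, ...] = ("sqrt", 0.3)
    cv_folds: int = 10
    scoring: str = "f1_weighted"

    def __post_init__(self) -> None:
        for name in ("n_trees", "max_depth", "min_samples_split", "max_features"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid axis {name} is empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def as_param_grid(self) -> dict:
        return {
            "n_estimators": list(self.n_trees),
            "max_depth": list(self.max_depth),
            "min_samples_split": list(self.min_samples_split),
            "max_features": list(self.max_features),
        }


#: A one-point grid for quick smoke runs and permutation replicates.
SMALL_RF_GRID = RFGrid(
    n_trees=(100,), max_depth=(None,), min_samples_split=(2,),
    max_features=("sqrt",), cv_folds=3,
)


# ---------------------------------------------------------------------------
# metrics


def weighted_f1(y_true, y_pred) -> float:
    """Class-size-weighted mean of per-class F1 scores.

    F1 of a class with no true and no predicted members is defined as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    classes = np.unique(y_true)
    total = 0.0
    for c in classes:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        total += (y_true == c).sum() * f1
    return float(total / y_true.size)


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, (1/n) sum |A - F| / |A| * 100."""
    A = np.asarray(actual, dtype=float)
    F = np.asarray(predicted, dtype=float)
    if A.size == 0:
        raise ValueError("empty input")
    if A.shape != F.shape:
        raise ValueError("actual and predicted must be aligned")
    if (A == 0).any():
        raise ValueError("MAPE undefined: an actual value is exactly 0")
    return float(np.mean(np.abs((A - F) / A)) * 100.0)


# ---------------------------------------------------------------------------
# model fitting


def tune_random_forest(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    grid: RFGrid | None = None,
    seed: int = 0,
):
    """Exhaustive grid search with stratified K-fold CV on weighted F1.

    Returns the refit best estimator and its chosen hyperparameters.
    """
    grid = grid or RFGrid()
    y = pd.Series(y_train).astype(int)
    counts = y.value_counts()
    cv_folds = grid.cv_folds
    if counts.min() < cv_folds:
        raise ValueError(
            f"need >= {cv_folds} samples per class for {cv_folds}-fold CV; "
            f"smallest class has {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        grid.as_param_grid(),
        scoring=grid.scoring,
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X_train.to_numpy(dtype=float), y.to_numpy())
    return search.best_estimator_, dict(search.best_params_)


def fit_and_score(
    X: pd.DataFrame,
    y: pd.Series,
    train_idx: pd.Index,
    test_idx: pd.Index,
    grid: RFGrid | None = None,
    seed: int = 0,
) -> float:
    """Tune on the training split, report weighted F1 on the test split."""
    model, _ = tune_random_forest(X.loc[train_idx], y.loc[train_idx], grid, seed)
    pred = model.predict(X.loc[test_idx].to_numpy(dtype=float))
    return weighted_f1(y.loc[test_idx].astype(int).to_numpy(), pred)


def random_baseline(
    X: pd.DataFrame,
    y: pd.Series,
    n_reps: int = 10,
    seed: int = 0,
    grid: RFGrid | None = None,
    test_fraction: float = 0.2,
) -> float:
    """Mean test weighted F1 over datasets with permuted feature columns.

    Each replicate independently permutes every feature column (severing
    any feature-label association while preserving marginal distributions)
    and runs the identical split/tune/test pipeline.  The returned mean is
    the dashed-line chance reference a real dataset must beat.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    grid = grid or SMALL_RF_GRID
    rng = np.random.default_rng(seed)
    scores = []
    for rep in range(n_reps):
        perm = X.apply(lambda col: rng.permutation(col.to_numpy()), axis=0)
        rep_seed = int(rng.integers(2**31 - 1))
        tr, te = split_train_test(perm, y, test_fraction, seed=rep_seed)
        scores.append(fit_and_score(perm, y, tr, te, grid, seed=rep_seed))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# benchmark orchestration


@dataclass
class BenchmarkConfig:
    response: str
    predictor_set: str
    spec: PreprocessSpec


def enumerate_benchmark_configs(
    responses: Sequence[str] = RESPONSES,
    levels: Sequence[str] = RANKS,
    nm_indices: Sequence[int] = tuple(range(1, 21)),
    predictor_sets: Sequence[str] = ("ALL-OTU",),
    augment_options: Sequence[bool] = (False,),
) -> list[BenchmarkConfig]:
    """The full factorial of benchmark runs.

    With the 6 responses, 5 ranks, all 20 NM variants and the ALL-OTU
    predictor set this enumerates the 600-configuration benchmark.
    """
    return [
        BenchmarkConfig(
            response=r,
            predictor_set=ps,
            spec=PreprocessSpec.from_nm_index(nm, level=level, augment=aug),
        )
        for r in responses
        for ps in predictor_sets
        for aug in augment_options
        for level in levels
        for nm in nm_indices
    ]


def _binarize(response: str, values: pd.Series, varieties: pd.Series) -> pd.Series:
    if response in DISEASE_RESPONSES:
        return binarize_disease(values)
    return binarize_yield(values, varieties)


def run_benchmark(
    counts: OTUTable,
    taxonomy,
    metadata: pd.DataFrame,
    responses: pd.DataFrame,
    configs: Iterable[BenchmarkConfig],
    env: pd.DataFrame | None = None,
    grid: RFGrid | None = None,
    seed: int = 0,
    min_prevalence: int = 15,
    augment_target: int = 400,
    with_baseline: bool = False,
    baseline_reps: int = 5,
    fs_config: FeatureSelectionConfig | None = None,
    zero_cfg: ZeroReplacementConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline for every configuration; one tidy row each.

    Per configuration: aggregate to the requested rank, prevalence-filter,
    zero-replace and normalize, binarize the response, split 80/20
    stratified, optionally augment the training split (with a leakage
    assertion), feature-select on training data only when the predictor set
    needs scores, tune a random forest, and score the held-out test set.
    Stage failures are recorded per row; the run continues.
    """
    grid = grid or SMALL_RF_GRID
    rows = []
    for cfg in configs:
        record = {
            "response": cfg.response,
            "predictor_set": cfg.predictor_set,
            "level": cfg.spec.level,
            "nm_index": cfg.spec.nm_index,
            "nm_label": cfg.spec.nm_label,
            "norm_method": cfg.spec.norm_method,
            "zero_method": cfg.spec.zero_method,
            "augment": cfg.spec.augment,
            "weighted_f1": np.nan,
            "baseline_f1": np.nan,
            "error": "",
        }
        try:
            record["weighted_f1"] = _run_one(
                counts, taxonomy, metadata, responses, cfg, grid, seed,
                min_prevalence, augment_target, fs_config, zero_cfg,
            )
            if with_baseline:
                table = aggregate_to_level(counts, taxonomy, cfg.spec.level)
                table = filter_by_prevalence(table, min_prevalence)
                X = apply_nm(table, cfg.spec, zero_cfg, rarefy_seed=seed)
                y = _binarize(
                    cfg.response,
                    responses[cfg.response],
                    metadata["variety"],
                ).dropna()
                X = X.loc[y.index]
                record["baseline_f1"] = random_baseline(
                    X, y, n_reps=baseline_reps, seed=seed, grid=grid
                )
        except Exception as exc:  # noqa: BLE001 - per-row failure capture
            record["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(record)
    return pd.DataFrame(rows)


def _run_one(
    counts, taxonomy, metadata, responses, cfg, grid, seed,
    min_prevalence, augment_target, fs_config, zero_cfg,
) -> float:
    table = aggregate_to_level(counts, taxonomy, cfg.spec.level)
    table = filter_by_prevalence(table, min_prevalence)
    X = apply_nm(table, cfg.spec, zero_cfg, rarefy_seed=seed)
    y = _binarize(cfg.response, responses[cfg.response], metadata["variety"]).dropna()
    X = X.loc[y.index]
    varieties = metadata.loc[y.index, "variety"]

    train_idx, test_idx = split_train_test(X, y, seed=seed)
    X_train, y_train = X.loc[train_idx], y.loc[train_idx].astype(int)

    if cfg.spec.augment:
        X_train, y_train, provenance = augment_training_set(
            X_train,
            y_train,
            varieties.loc[train_idx],
            target_per_label=augment_target,
            seed=seed,
            clip_negative=cfg.spec.norm_method != "clr",
        )
        assert leakage_check(X_train.index, test_idx, provenance)

    if cfg.predictor_set != "ALL-OTU":
        X_sel = _select_predictors(
            cfg.predictor_set, X, X_train, y_train, train_idx, fs_config, seed
        )
        X_train = X_sel.loc[X_train.index]
        X_test = X_sel.loc[test_idx]
    else:
        X_test = X.loc[test_idx]

    model, _ = tune_random_forest(X_train, y_train, grid, seed)
    pred = model.predict(X_test.to_numpy(dtype=float))
    return weighted_f1(y.loc[test_idx].astype(int).to_numpy(), pred)


def _select_predictors(
    name, X, X_train, y_train, train_idx, fs_config, seed
) -> pd.DataFrame:
    """Score taxa on the (pre-augmentation) training rows and subset X."""
    fs_config = fs_config or FeatureSelectionConfig(seed=seed)
    X_fit = X.loc[train_idx]
    y_fit = y_train.loc[train_idx].astype(int)
    ml = ml_feature_scores(X_fit, y_fit, fs_config)
    net0 = estimate_class_network(X_fit[y_fit == 0], fs_config.network)
    net1 = estimate_class_network(X_fit[y_fit == 1], fs_config.network)
    net = network_degree_difference(net0, net1, fs_config.top_fraction)
    scores = combine_feature_scores(
        ml["ml_selected"].reindex(X.columns),
        net["net_selected"].reindex(X.columns),
    )
    return build_predictor_set(name, X, scores=scores, seed=seed)
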