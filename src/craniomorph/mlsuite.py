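"""Classifier benchmark: splits, preprocessing, hyperparameter searches,
tiered configurations, and precision/recall/F1 + timing evaluation.

Three model families are benchmarked on the descriptor tables: a CART
decision tree (DT), a random forest (RF) and a multilayer perceptron
(MLP).  Search spaces and the high/low-performance configurations are
fixed constants of the suite; see :data:`SEARCH_SPACES` and
:data:`TIER_CONFIGS`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import (
    GridSearchCV,
    GroupShuffleSplit,
    ParameterGrid,
    RandomizedSearchCV,
    train_test_split,
)
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from craniomorph.descriptors import DESCRIPTOR_COLUMNS
from craniomorph.errors import CraniomorphError

MODELS = ("DT", "RF", "MLP")

#: The three canonical train/validation/test ratio presets.
RATIO_PRESETS: dict[str, tuple[float, float, float]] = {
    "60/20/20": (0.60, 0.20, 0.20),
    "70/15/15": (0.70, 0.15, 0.15),
    "90/5/5": (0.90, 0.05, 0.05),
}


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partitioning scheme."""

    ratios: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0
    stratified: bool = True
    group_level: str = "sample"  # or "base"

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise CraniomorphError(f"split ratios {self.ratios} do not sum to 1")
        if self.group_level not in ("sample", "base"):
            raise CraniomorphError(f"unknown group_level {self.group_level!r}")


@dataclass(frozen=True)
class SearchSpace:
    """One model's hyperparameter search definition."""

    model: str
    grid: Mapping[str, list]
    search_type: str  # "randomized" | "exhaustive"
    n_iter: int = 0  # randomized draws (ignored for exhaustive)
    cv_folds: int = 3

    @property
    def n_candidates(self) -> int:
        if self.search_type == "randomized":
            return self.n_iter
        return len(ParameterGrid(dict(self.grid)))

    @property
    def planned_fits(self) -> int:
        return self.n_candidates * self.cv_folds


# 'auto' feature subsampling is deprecated upstream; for classification it
# equals sqrt, so the token maps to 'sqrt' while keeping the list length
# (and hence the combination count) intact.
SEARCH_SPACES: dict[str, SearchSpace] = {
    "DT": SearchSpace(
        model="DT",
        grid={
            "max_depth": list(range(3, 21)),
            "min_samples_split": list(range(2, 21)),
            "min_samples_leaf": list(range(1, 21)),
        },
        search_type="randomized",
        n_iter=100,
    ),
    "RF": SearchSpace(
        model="RF",
        grid={
            "n_estimators": [50, 100, 150, 200],
            "max_depth": [3, 5, 10, 15, 20],
            "min_samples_split": [2, 5, 10, 15],
            "min_samples_leaf": [1, 2, 5, 10],
            "max_features": ["sqrt", "sqrt", "log2"],  # ['auto','sqrt','log2']
        },
        search_type="exhaustive",
    ),
    "MLP": SearchSpace(
        model="MLP",
        grid={
            "hidden_layer_sizes": [
                (4,),
                (100, 50),
                (100, 100, 50),
                (200, 100, 50),
                (200, 200, 100, 50),
                (300, 200, 100, 50),
            ],
            "activation": ["relu", "tanh"],
            "solver": ["adam", "sgd"],
            "learning_rate": ["constant", "adaptive"],
        },
        search_type="exhaustive",
    ),
}


@dataclass(frozen=True)
class ModelConfig:
    """A named hyperparameter set of one model family."""

    model: str
    params: Mapping[str, object]
    performance_tier: str = "custom"  # "high" | "low" | "custom"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise CraniomorphError(f"unknown model {self.model!r}")


#: High/low-performance configurations.  Where a range is quoted for the
#: forest size (50-100 high, 50-200 low) the shared value 100 is used.
#: The low-tier MLP is the single-hidden-layer SGD variant; the deeper
#: SGD alternative is kept alongside.
TIER_CONFIGS: dict[tuple[str, str], ModelConfig] = {
    ("DT", "high"): ModelConfig(
        "DT", {"min_samples_split": 3, "min_samples_leaf": 1, "max_depth": 19}, "high"
    ),
    ("DT", "low"): ModelConfig(
        "DT", {"min_samples_split": 20, "min_samples_leaf": 18, "max_depth": 3}, "low"
    ),
    ("RF", "high"): ModelConfig(
        "RF",
        {
            "n_estimators": 100,
            "max_depth": 10,
            "max_features": "sqrt",
            "min_samples_leaf": 1,
            "min_samples_split": 2,
        },
        "high",
    ),
    ("RF", "low"): ModelConfig(
        "RF",
        {
            "n_estimators": 100,
            "max_depth": 3,
            "max_features": "log2",
            "min_samples_leaf": 10,
            "min_samples_split": 2,
        },
        "low",
    ),
    ("MLP", "high"): ModelConfig(
        "MLP",
        {
            "hidden_layer_sizes": (100, 50),
            "activation": "relu",
            "solver": "adam",
            "learning_rate": "constant",
        },
        "high",
    ),
    ("MLP", "low"): ModelConfig(
        "MLP",
        {
            "hidden_layer_sizes": (4,),
            "activation": "relu",
            "solver": "sgd",
            "learning_rate": "constant",
        },
        "low",
    ),
}

#: Alternative reading of the low-tier MLP (two hidden layers, SGD).
MLP_LOW_ALT = ModelConfig(
    "MLP",
    {
        "hidden_layer_sizes": (100, 50),
        "activation": "relu",
        "solver": "sgd",
        "learning_rate": "constant",
    },
    "low",
)


def make_estimator(model: str, params: Mapping[str, object], seed: int = 0):
    """Instantiate the scikit-learn estimator for a model family."""
    params = dict(params)
    if model == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if model == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if model == "MLP":
        return MLPClassifier(max_iter=1000, random_state=seed, **params)
    raise CraniomorphError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Splitting and preprocessing
# ---------------------------------------------------------------------------


def split_dataset(table: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Assign a disjoint, exhaustive train/validation/test tag per row."""
    if table.empty:
        raise CraniomorphError("cannot split an empty table")
    df = table.copy()
    idx = np.arange(len(df))
    y = df["label_code"].to_numpy()
    r_train, r_val, r_test = spec.ratios

    if spec.group_level == "base":
        groups = df["base_id"].to_numpy()
        gss = GroupShuffleSplit(n_splits=1, test_size=r_test, random_state=spec.seed)
        trainval_idx, test_idx = next(gss.split(idx, y, groups))
        rel_val = r_val / (r_train + r_val)
        gss2 = GroupShuffleSplit(n_splits=1, test_size=rel_val, random_state=spec.seed + 1)
        tr, va = next(gss2.split(trainval_idx, y[trainval_idx], groups[trainval_idx]))
        train_idx, val_idx = trainval_idx[tr], trainval_idx[va]
    else:
        strat = y if spec.stratified else None
        trainval_idx, test_idx = train_test_split(
            idx, test_size=r_test, random_state=spec.seed, stratify=strat
        )
        strat2 = y[trainval_idx] if spec.stratified else None
        rel_val = r_val / (r_train + r_val)
        train_idx, val_idx = train_test_split(
            trainval_idx, test_size=rel_val, random_state=spec.seed, stratify=strat2
        )

    split = np.empty(len(df), dtype=object)
    split[train_idx] = "train"
    split[val_idx] = "validation"
    split[test_idx] = "test"
    df["split"] = split
    return df


def _partition(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    parts = {name: table[table["split"] == name] for name in ("train", "validation", "test")}
    if parts["train"].empty:
        raise CraniomorphError("table has no training partition; run split_dataset first")
    return parts


def preprocess(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    test: pd.DataFrame,
    model: str,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Impute missing descriptors by training-column means; standardise for MLP.

    All statistics come from the training partition only.  Trees get
    imputed, unscaled features.
    """
    cols = DESCRIPTOR_COLUMNS
    X_train = train[cols]
    all_missing = X_train.columns[X_train.isna().all()]
    if len(all_missing):
        raise CraniomorphError(
            f"descriptor column(s) entirely missing in training data: "
            f"{list(all_missing)[:5]}"
        )
    imputer = SimpleImputer(strategy="mean").fit(X_train.to_numpy())
    steps = [imputer]
    if model == "MLP":
        steps.append(StandardScaler().fit(imputer.transform(X_train.to_numpy())))

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df.copy()
        X = df[cols].to_numpy()
        for step in steps:
            X = step.transform(X)
        out = df.copy()
        out[cols] = X
        return out

    return _apply(train), _apply(validation), _apply(test)


# ---------------------------------------------------------------------------
# Search and evaluation
# ---------------------------------------------------------------------------


def run_search(
    space: SearchSpace,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Execute the planned search; return best config and a per-fit log.

    The log has exactly ``space.planned_fits`` rows (one per candidate
    x cross-validation fold) with the fold test score.
    """
    if not space.grid:
        raise CraniomorphError("empty search grid")
    base = make_estimator(space.model, {}, seed=seed)
    common = dict(cv=space.cv_folds, scoring="accuracy", n_jobs=1, refit=False)
    if space.search_type == "randomized":
        search = RandomizedSearchCV(
            base, dict(space.grid), n_iter=space.n_iter, random_state=seed, **common
        )
    else:
        search = GridSearchCV(base, dict(space.grid), **common)
    search.fit(X, y)

    cvres = search.cv_results_
    records = []
    for cand, params in enumerate(cvres["params"]):
        for fold in range(space.cv_folds):
            records.append(
                {
                    "candidate": cand,
                    "fold": fold,
                    "score": cvres[f"split{fold}_test_score"][cand],
                    **{f"param_{k}": v for k, v in params.items()},
                }
            )
    log = pd.DataFrame.from_records(records)
    best = cvres["params"][int(np.argmax(cvres["mean_test_score"]))]
    return ModelConfig(space.model, best, "custom"), log


@dataclass
class EvalResult:
    """Metrics, confusion matrix and timing of one model x split x config run."""

    config: ModelConfig
    split: SplitSpec
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame
    confusion: np.ndarray
    fit_seconds: float
    predict_seconds: float
    weighted: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def train_eval(
    config: ModelConfig,
    table: pd.DataFrame,
    seed: int = 0,
    split: SplitSpec | None = None,
) -> EvalResult:
    """Fit on the training partition, report macro metrics on the test one."""
    parts = _partition(table)
    labels = np.sort(table["label_code"].unique())
    missing = set(labels) - set(parts["train"]["label_code"].unique())
    if missing:
        raise CraniomorphError(
            f"class(es) absent from training partition: {sorted(missing)}"
        )
    train, validation, test = preprocess(
        parts["train"], parts["validation"], parts["test"], config.model
    )
    X_train = train[DESCRIPTOR_COLUMNS].to_numpy()
    y_train = train["label_code"].to_numpy()
    X_test = test[DESCRIPTOR_COLUMNS].to_numpy()
    y_test = test["label_code"].to_numpy()

    est = make_estimator(config.model, config.params, seed=seed)
    t0 = time.perf_counter()
    est.fit(X_train, y_train)
    fit_s = time.perf_counter() - t0
    t0 = time.perf_counter()
    y_pred = est.predict(X_test)
    pred_s = time.perf_counter() - t0

    prec, rec, f1, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=labels, average="macro", zero_division=0
    )
    w_prec, w_rec, w_f1, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=labels, average="weighted", zero_division=0
    )
    pc_prec, pc_rec, pc_f1, pc_n = precision_recall_fscore_support(
        y_test, y_pred, labels=labels, average=None, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": pc_prec, "recall": pc_rec, "f1": pc_f1, "support": pc_n},
        index=pd.Index(labels, name="label_code"),
    )
    conf = confusion_matrix(y_test, y_pred, labels=labels)
    return EvalResult(
        config=config,
        split=split or SplitSpec(),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        per_class=per_class,
        confusion=conf,
        fit_seconds=fit_s,
        predict_seconds=pred_s,
        weighted={"precision": float(w_prec), "recall": float(w_rec), "f1": float(w_f1)},
        seed=seed,
    )


def run_experiment_matrix(
    table: pd.DataFrame,
    seeds: Sequence[int] = (0,),
    group_level: str = "sample",
    models: Sequence[str] = MODELS,
    tiers: Sequence[str] = ("high", "low"),
) -> dict:
    """Evaluate model x tier x ratio-preset; metrics averaged over seeds.

    Returns ``{"results": [EvalResult...], "metrics": DataFrame,
    "timing": DataFrame}`` where the metrics frame mirrors the
    ratio-by-model layout with high/low precision, recall and F1
    columns and the timing frame holds total fit+predict seconds.
    """
    results: list[EvalResult] = []
    rows = []
    timing_rows = []
    for ratio_name, ratios in RATIO_PRESETS.items():
        for seed in seeds:
            spec = SplitSpec(ratios=ratios, seed=seed, group_level=group_level)
            tagged = split_dataset(table, spec)
            for model in models:
                for tier in tiers:
                    cfg = TIER_CONFIGS[(model, tier)]
                    res = train_eval(cfg, tagged, seed=seed, split=spec)
                    results.append(res)

    for ratio_name in RATIO_PRESETS:
        for model in models:
            row = {"ratios": ratio_name, "model": model}
            trow = {"ratios": ratio_name, "model": model}
            for tier in tiers:
                sel = [
                    r
                    for r in results
                    if r.config.model == model
                    and r.config.performance_tier == tier
                    and RATIO_PRESETS[ratio_name] == r.split.ratios
                ]
                row[f"precision_{tier}"] = float(np.mean([r.precision for r in sel]))
                row[f"recall_{tier}"] = float(np.mean([r.recall for r in sel]))
                row[f"f1_{tier}"] = float(np.mean([r.f1 for r in sel]))
                trow[f"seconds_{tier}"] = float(
                    np.mean([r.fit_seconds + r.predict_seconds for r in sel])
                )
            rows.append(row)
            timing_rows.append(trow)
    return {
        "results": results,
        "metrics": pd.DataFrame(rows),
        "timing": pd.DataFrame(timing_rows),
    }
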