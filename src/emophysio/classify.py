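"""Subject-stratified classification benchmark.

Seven model families (KNN, decision tree, logistic regression, RBF SVM, LDA,
random forest, AdaBoost) are evaluated with 10-fold cross-validation whose
folds partition subjects, so no subject's rows ever straddle a fold boundary.
Hyperparameters are grid-searched by mean fold accuracy. Median imputation
and standardization are fitted inside each training fold. The benchmark
sweeps Square Method overlap thresholds over four conditions: all stimulation
phases together (with a held-out 7-subject test set) and the three per-phase
subsets (cross-validation only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import square
from .features import split_by_subject
from .protocol import Phase

__all__ = [
    "BenchmarkConfig",
    "CVResult",
    "BenchmarkResult",
    "subject_folds",
    "run_cv",
    "run_benchmark",
    "attention_only_baseline",
    "MODEL_GRIDS",
]

MODEL_GRIDS: dict[str, dict] = {
    "KNN": {"clf__n_neighbors": [1, 3, 5, 7, 9]},
    "DT": {"clf__max_depth": [2, 4, 8, None]},
    "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "SVM": {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale", 0.01, 0.1]},
    "LDA": {},
    "RF": {"clf__n_estimators": [100, 300], "clf__max_depth": [4, None]},
    "ADB": {"clf__n_estimators": [50, 100, 200]},
}


def _make_model(name: str, seed: int):
    if name == "KNN":
        clf = KNeighborsClassifier()
    elif name == "DT":
        clf = DecisionTreeClassifier(random_state=seed)
    elif name == "LR":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif name == "SVM":
        clf = SVC(kernel="rbf", random_state=seed)
    elif name == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif name == "RF":
        clf = RandomForestClassifier(random_state=seed)
    elif name == "ADB":
        clf = AdaBoostClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown model {name}")
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("clf", clf),
    ])


@dataclass
class BenchmarkConfig:
    models: tuple[str, ...] = tuple(MODEL_GRIDS)
    grids: dict = field(default_factory=lambda: dict(MODEL_GRIDS))
    cv_folds: int = 10
    n_test_subjects: int = 7
    thresholds: tuple[float, ...] | None = None  # None -> sweep grid incl. LO
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_GRIDS)
        if unknown:
            raise ValueError(f"unknown models: {unknown}")


def subject_folds(
    subjects: np.ndarray, labels: np.ndarray, n_folds: int, seed: int,
    max_redraws: int = 20,
) -> list[np.ndarray]:
    """Partition subjects into folds; return per-fold row index masks.

    A fold missing one of the classes is re-drawn with a fresh seed (each
    subject normally contributes one row per class, so this is rare).
    """
    uniq = np.array(sorted(set(subjects)))
    n_folds = min(n_folds, len(uniq))
    classes = set(labels)
    for attempt in range(max_redraws):
        rng = np.random.default_rng(seed + attempt)
        order = rng.permutation(uniq)
        groups = np.array_split(order, n_folds)
        masks = [np.isin(subjects, g) for g in groups]
        if all(set(labels[m]) == classes for m in masks):
            return masks
    raise RuntimeError("could not draw subject folds covering every class")


@dataclass
class CVResult:
    model: str
    mean_accuracy: float
    sd_accuracy: float
    best_params: dict
    fold_accuracies: np.ndarray


def run_cv(
    table: pd.DataFrame,
    feature_cols: list[str],
    config: BenchmarkConfig,
    label_col: str = "quadrant",
) -> dict[str, CVResult]:
    """Grid-searched, subject-stratified CV accuracies for every model."""
    if not feature_cols:
        raise ValueError("no features to classify on")
    X = table[feature_cols].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    subjects = table["subject_id"].to_numpy()
    masks = subject_folds(subjects, y, config.cv_folds, config.seed)

    results: dict[str, CVResult] = {}
    for name in config.models:
        grid = list(ParameterGrid(config.grids.get(name, {}))) or [{}]
        best: CVResult | None = None
        for params in grid:
            accs = []
            for m in masks:
                model = _make_model(name, config.seed)
                model.set_params(**params)
                model.fit(X[~m], y[~m])
                accs.append(model.score(X[m], y[m]))
            accs = np.array(accs)
            if best is None or accs.mean() > best.mean_accuracy:
                best = CVResult(name, float(accs.mean()), float(accs.std(ddof=1)),
                                params, accs)
        results[name] = best
    return results


@dataclass
class BenchmarkResult:
    """Tidy per-(condition, threshold, model) summary plus the best test run."""

    records: pd.DataFrame
    selections: dict  # (condition, threshold) -> SMResult
    params_map: dict  # (condition, threshold, model) -> best hyperparameters
    best_condition_all: dict | None = None  # threshold/model/test accuracy

    def best_rows(self) -> pd.DataFrame:
        idx = self.records.groupby(["condition", "threshold"])["mean_accuracy"].idxmax()
        return self.records.loc[idx].reset_index(drop=True)


def _sweep(table, feature_cols, config, condition, records, selections, params_map):
    thresholds = config.thresholds
    if thresholds is None:
        thresholds = square.threshold_grid(table, seed=config.seed,
                                           feature_cols=feature_cols)
    for thr in thresholds:
        sm = square.select_features(table, thr, seed=config.seed,
                                    feature_cols=feature_cols)
        selections[(condition, thr)] = sm
        if not sm.selected:
            continue
        for name, res in run_cv(table, sm.selected, config).items():
            params_map[(condition, thr, name)] = res.best_params
            records.append({
                "condition": condition, "threshold": thr, "model": name,
                "mean_accuracy": res.mean_accuracy, "sd_accuracy": res.sd_accuracy,
                "n_features": len(sm.selected), "best_params": str(res.best_params),
            })


def run_benchmark(
    table: pd.DataFrame,
    config: BenchmarkConfig | None = None,
    feature_cols: list[str] | None = None,
) -> BenchmarkResult:
    """The four-condition benchmark over the threshold sweep.

    Condition "all" uses a subject-held-out test set: the Square Method and
    every fitted statistic see training rows only, and the best
    (threshold, model) by validation accuracy is retrained on the full
    training side and scored once on the test side. The three per-phase
    conditions are evaluated by cross-validation alone.
    """
    config = config or BenchmarkConfig()
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in
                        ("subject_id", "phase", "session", "valence_half",
                         "quadrant", "flags")]
    records: list[dict] = []
    selections: dict = {}
    params_map: dict = {}

    train, test = split_by_subject(table, config.n_test_subjects, config.seed)
    _sweep(train, feature_cols, config, "all", records, selections, params_map)

    for phase in Phase:
        sub = table[table["phase"] == phase.value]
        _sweep(sub, feature_cols, config, phase.value.lower(), records, selections,
               params_map)

    rec_df = pd.DataFrame(records)
    best_all = None
    all_rows = rec_df[rec_df["condition"] == "all"]
    if len(all_rows):
        top = all_rows.loc[all_rows["mean_accuracy"].idxmax()]
        sm = selections[("all", top["threshold"])]
        model = _make_model(top["model"], config.seed)
        model.set_params(**params_map[("all", top["threshold"], top["model"])])
        Xtr = train[sm.selected].to_numpy(float)
        Xte = test[sm.selected].to_numpy(float)
        model.fit(Xtr, train["quadrant"].to_numpy())
        test_acc = float(model.score(Xte, test["quadrant"].to_numpy()))
        best_all = {
            "threshold": float(top["threshold"]), "model": top["model"],
            "validation_accuracy": float(top["mean_accuracy"]),
            "test_accuracy": test_acc, "n_features": int(top["n_features"]),
        }
    return BenchmarkResult(rec_df, selections, params_map, best_all)


def attention_only_baseline(
    table: pd.DataFrame,
    config: BenchmarkConfig | None = None,
    feature: str = "eeg_parietal_beta_theta",
) -> dict[str, CVResult]:
    """The model sweep using only the parietal attention index."""
    config = config or BenchmarkConfig()
    if feature not in table.columns:
        raise ValueError(f"column {feature} not present")
    return run_cv(table, [feature], config)
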