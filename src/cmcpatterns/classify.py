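"""Leakage-controlled multiclass classification of CMC patterns.

A multiclass random forest predicts a participant's pattern label from
baseline covariates, evaluated by stratified outer cross-validation
repeated several times, with nested inner CV for hyperparameter tuning.
Every data-dependent step — imputation, standardisation, one-hot
encoding and minority oversampling (SMOTE) — is fitted strictly inside
the training partition of whichever split is being evaluated, so held
out rows never influence the fitted pipeline.

SMOTE is implemented here directly from its defining contract: each
minority class is upsampled to the majority count by convex
combinations of a random class member and one of its k nearest
same-class neighbours in the preprocessed feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CVConfig",
    "FoldResult",
    "MetricsSummary",
    "Preprocessor",
    "preprocess_fit",
    "preprocess_apply",
    "smote_balance",
    "weighted_metrics",
    "run_nested_cv",
    "leaky_cv_smote_before_split",
    "DEFAULT_GRID",
    "QUICK_GRID",
]

#: Hyperparameter grid used by default (a documented convention; tuning
#: is selected by inner-CV weighted F1).
DEFAULT_GRID = tuple(
    {"n_estimators": t, "max_depth": d, "min_samples_leaf": l}
    for t in (200, 500)
    for d in (None, 10)
    for l in (1, 5)
)

#: Reduced grid for quick-mode runs.
QUICK_GRID = (
    {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1},
    {"n_estimators": 100, "max_depth": 10, "min_samples_leaf": 5},
)


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified nested cross-validation settings."""

    outer_folds: int = 10
    repeats: int = 5
    inner_folds: int = 5
    seed: int = 0
    grid: tuple = DEFAULT_GRID
    smote_k_neighbors: int = 5

    def validate(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    @classmethod
    def quick(cls, seed: int = 0) -> "CVConfig":
        """Small profile (5x2 outer CV, 3-fold inner, reduced grid)."""
        return cls(outer_folds=5, repeats=2, inner_folds=3, seed=seed, grid=QUICK_GRID)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


class Preprocessor:
    """Train-fitted imputation, scaling and one-hot encoding.

    Continuous columns: median-impute then centre/scale by train
    statistics (a zero-variance column maps to zeros).  Categorical
    columns: mode-impute then one-hot over train-observed levels; a test
    level unseen in training maps to an all-zero indicator block.
    """

    def __init__(self) -> None:
        self.continuous_: list[str] = []
        self.categorical_: list[str] = []
        self.medians_: dict[str, float] = {}
        self.means_: dict[str, float] = {}
        self.scales_: dict[str, float] = {}
        self.modes_: dict[str, str] = {}
        self.levels_: dict[str, list[str]] = {}
        self.feature_names_: list[str] = []
        self.n_fit_rows_: int = 0

    def fit(self, train: pd.DataFrame) -> "Preprocessor":
        self.n_fit_rows_ = len(train)
        for col in train.columns:
            s = train[col]
            if s.isna().all():
                raise ValueError(f"column {col!r} is entirely missing in the training data")
            if pd.api.types.is_numeric_dtype(s):
                self.continuous_.append(col)
                vals = s.astype(float)
                self.medians_[col] = float(vals.median())
                filled = vals.fillna(self.medians_[col])
                self.means_[col] = float(filled.mean())
                sd = float(filled.std(ddof=0))
                self.scales_[col] = sd if sd > 0 else 1.0
            else:
                self.categorical_.append(col)
                s = s.astype("object")
                mode = s.mode(dropna=True)
                self.modes_[col] = str(mode.iloc[0])
                self.levels_[col] = sorted(str(v) for v in s.dropna().unique())
        self.feature_names_ = list(self.continuous_) + [
            f"{col}.{lev}" for col in self.categorical_ for lev in self.levels_[col]
        ]
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        n = len(table)
        blocks = []
        for col in self.continuous_:
            vals = table[col].astype(float).fillna(self.medians_[col]).to_numpy()
            blocks.append(((vals - self.means_[col]) / self.scales_[col])[:, None])
        for col in self.categorical_:
            s = table[col].astype("object")
            s = s.where(s.notna(), self.modes_[col]).astype(str)
            block = np.zeros((n, len(self.levels_[col])))
            for j, lev in enumerate(self.levels_[col]):
                block[:, j] = (s == lev).to_numpy(dtype=float)
            blocks.append(block)
        return np.hstack(blocks) if blocks else np.empty((n, 0))


def preprocess_fit(train: pd.DataFrame) -> Preprocessor:
    """Fit imputation/scaling/encoding on a training partition only."""
    return Preprocessor().fit(train)


def preprocess_apply(transformer: Preprocessor, table: pd.DataFrame) -> np.ndarray:
    """Apply a fitted transformer; never refits."""
    return transformer.transform(table)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample every minority class to the majority count.

    Synthetic samples are convex combinations ``x + u * (nbr - x)`` with
    ``u ~ U(0, 1)`` between a random minority member and one of its
    ``min(k_neighbors, class size - 1)`` nearest same-class neighbours.
    Classes of size 1 cannot be interpolated and are skipped with a
    warning; an empty class is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y) or len(X) == 0:
        raise ValueError("X and y must be non-empty and of equal length")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() == 0:  # pragma: no cover - np.unique cannot yield this
        raise ValueError("empty class")
    majority = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = majority - cnt
        if need == 0:
            continue
        if cnt == 1:
            warnings.warn(
                f"class {cls!r} has a single member; SMOTE skipped for it",
                stacklevel=2,
            )
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        nbr_idx = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(0, k, size=need)
        gap = rng.random(need)[:, None]
        neighbours = Xc[nbr_idx[base, pick]]
        synthetic = Xc[base] + gap * (neighbours - Xc[base])
        new_X.append(synthetic)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def weighted_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy plus support-weighted precision, recall and F1.

    Per-class precision/recall/F1 are averaged weighted by true-class
    support.  A true class never predicted contributes precision 0 (with
    a warning).  Note weighted recall equals plain accuracy; both are
    reported for transparency.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    missing = set(np.unique(y_true)) - set(np.unique(y_pred))
    if missing:
        warnings.warn(
            f"classes never predicted (precision 0): {sorted(map(str, missing))}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
    }


@dataclass
class MetricsSummary:
    """Mean and sd of the weighted metrics across all outer folds."""

    mean: dict[str, float]
    sd: dict[str, float]
    per_fold: pd.DataFrame  # columns: repeat, fold, accuracy..f1

    @classmethod
    def from_folds(cls, rows: list[dict]) -> "MetricsSummary":
        per_fold = pd.DataFrame(rows)
        metric_cols = ["accuracy", "precision", "recall", "f1"]
        return cls(
            mean={m: float(per_fold[m].mean()) for m in metric_cols},
            sd={m: float(per_fold[m].std(ddof=1)) if len(per_fold) > 1 else 0.0
                for m in metric_cols},
            per_fold=per_fold,
        )


@dataclass
class FoldResult:
    """Everything retained from one outer evaluation fold."""

    repeat: int
    fold: int
    params: dict
    model: RandomForestClassifier
    preprocessor: Preprocessor
    train_ids: np.ndarray
    test_ids: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray  # (n_test, n_classes), column order = model.classes_
    X_test: np.ndarray  # preprocessed test matrix
    feature_names: list[str]


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------

_OTHER = "__other__"


def _strat_labels(y: np.ndarray, min_count: int) -> np.ndarray:
    """Merge classes rarer than ``min_count`` into one stratum for splitting.

    True labels are retained for training and scoring; only the split
    stratification uses the merged labels.
    """
    classes, counts = np.unique(y, return_counts=True)
    rare = {c for c, n in zip(classes, counts) if n < min_count}
    if rare:
        warnings.warn(
            f"classes {sorted(map(str, rare))} have fewer than {min_count} members; "
            "merged into one stratum for splitting (true labels kept for scoring)",
            stacklevel=3,
        )
    return np.array([_OTHER if v in rare else str(v) for v in y])


def _fold_seeds(seed: int, repeat: int, fold: int) -> tuple[int, int, int]:
    """Derive (inner, smote, model) substream seeds for one outer fold."""
    ss = np.random.SeedSequence([seed, repeat, fold])
    a, b, c = ss.generate_state(3)
    m = 2**31 - 1
    return int(a % m), int(b % m), int(c % m)


def _fit_once(
    train_df, y_train, params, smote_k, smote_seed, model_seed
) -> tuple[Preprocessor, RandomForestClassifier]:
    pre = preprocess_fit(train_df)
    X = pre.transform(train_df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xb, yb = smote_balance(X, y_train, k_neighbors=smote_k, seed=smote_seed)
    rf = RandomForestClassifier(random_state=model_seed, n_jobs=1, **params)
    rf.fit(Xb, yb)
    return pre, rf


def _inner_select(
    train_df, y_train, strat_train, config, inner_seed, smote_seed, model_seed
) -> dict:
    """Grid search by inner stratified CV; selection metric is weighted F1."""
    if len(config.grid) == 1:
        return dict(config.grid[0])
    inner = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=inner_seed % (2**32 - 1)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        splits = list(inner.split(np.zeros(len(y_train)), strat_train))
    best_score, best_params = -np.inf, dict(config.grid[0])
    for params in config.grid:
        scores = []
        for tr, va in splits:
            pre, rf = _fit_once(
                train_df.iloc[tr], y_train[tr], params,
                config.smote_k_neighbors, smote_seed, model_seed,
            )
            y_hat = rf.predict(pre.transform(train_df.iloc[va]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores.append(weighted_metrics(y_train[va], y_hat)["f1"])
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_params = score, dict(params)
    return best_params


def run_nested_cv(
    table: pd.DataFrame,
    labels,
    config: CVConfig = CVConfig(),
) -> tuple[MetricsSummary, list[FoldResult]]:
    """Repeated stratified outer CV with nested tuning and fold-internal SMOTE.

    For every repeat x outer fold: the outer-train partition is used for
    an inner stratified grid search (each inner fold refits
    preprocessing and SMOTE on its own training part), the winning
    hyperparameters are refitted on the full outer-train partition
    (preprocessed, SMOTE-balanced), and the untouched outer-test
    partition is preprocessed with the outer-train transformer and
    predicted.  Metrics are aggregated as mean (sd) over all
    ``repeats * outer_folds`` folds.
    """
    config.validate()
    y = np.asarray([str(v) for v in labels])
    if len(table) != len(y):
        raise ValueError("table and labels must align")
    table = table.reset_index(drop=True)
    strat = _strat_labels(y, config.outer_folds)

    outer = RepeatedStratifiedKFold(
        n_splits=config.outer_folds,
        n_repeats=config.repeats,
        random_state=config.seed,
    )
    fold_rows, fold_results = [], []
    for split_idx, (tr, te) in enumerate(outer.split(np.zeros(len(y)), strat)):
        repeat, fold = divmod(split_idx, config.outer_folds)
        inner_seed, smote_seed, model_seed = _fold_seeds(config.seed, repeat, fold)
        train_df, y_train = table.iloc[tr], y[tr]
        params = _inner_select(
            train_df, y_train, strat[tr], config, inner_seed, smote_seed, model_seed
        )
        pre, rf = _fit_once(
            train_df, y_train, params, config.smote_k_neighbors, smote_seed, model_seed
        )
        X_test = pre.transform(table.iloc[te])
        y_pred = rf.predict(X_test)
        proba = rf.predict_proba(X_test)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = weighted_metrics(y[te], y_pred)
        fold_rows.append({"repeat": repeat, "fold": fold, **metrics})
        fold_results.append(
            FoldResult(
                repeat=repeat, fold=fold, params=params, model=rf,
                preprocessor=pre, train_ids=tr.copy(), test_ids=te.copy(),
                y_true=y[te], y_pred=y_pred, proba=proba, X_test=X_test,
                feature_names=list(pre.feature_names_),
            )
        )
    return MetricsSummary.from_folds(fold_rows), fold_results


def leaky_cv_smote_before_split(
    table: pd.DataFrame,
    labels,
    config: CVConfig = CVConfig(),
) -> MetricsSummary:
    """Negative control: SMOTE applied to the FULL data before splitting.

    Preprocessing and oversampling are fitted once on all rows; the CV
    then splits only the original rows, but every fold's training set
    also receives all synthetic points — which were interpolated from
    the full data, held-out rows included.  Evaluation stays on original
    rows, so the metrics are directly comparable with
    :func:`run_nested_cv` and optimistically biased on imbalanced data.
    It exists only to demonstrate that bias; never use it for reporting.
    """
    config.validate()
    y = np.asarray([str(v) for v in labels])
    pre = preprocess_fit(table)  # leak: fitted on everything
    X = pre.transform(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xb, yb = smote_balance(X, y, config.smote_k_neighbors, seed=config.seed)
    X_synth, y_synth = Xb[len(X):], yb[len(X):]
    outer = RepeatedStratifiedKFold(
        n_splits=config.outer_folds, n_repeats=config.repeats, random_state=config.seed
    )
    params = dict(config.grid[0])
    rows = []
    for split_idx, (tr, te) in enumerate(outer.split(X, y)):
        repeat, fold = divmod(split_idx, config.outer_folds)
        _, _, model_seed = _fold_seeds(config.seed, repeat, fold)
        rf = RandomForestClassifier(random_state=model_seed, n_jobs=1, **params)
        # leak: synthetic points carry held-out information into training
        rf.fit(np.vstack([X[tr], X_synth]), np.concatenate([y[tr], y_synth]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = weighted_metrics(y[te], rf.predict(X[te]))
        rows.append({"repeat": repeat, "fold": fold, **metrics})
    return MetricsSummary.from_folds(rows)
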