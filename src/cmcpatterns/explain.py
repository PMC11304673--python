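"""Shapley explanation of the pattern classifier, computed within the CV loop.

Attributions are exact path-dependent Shapley values for tree ensembles
(the polynomial-time TreeSHAP recursion), computed in predicted
probability space: for each held-out row and each class, the per-feature
attributions plus a base value (the ensemble's expected predicted
probability) sum to the model's predicted probability for that row and
class.  Using the path-dependent formulation keeps the computation fully
deterministic and avoids choosing a background dataset: the conditional
expectations are taken over the training-sample cover fractions stored
in the fitted trees themselves.

Attributions are computed only on each fold's held-out partition and
pooled across all repeats and folds, so the explanation inherits the
leakage control of the cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.ensemble import RandomForestClassifier

from .classify import FoldResult

__all__ = [
    "ShapResult",
    "forest_shap_values",
    "compute_shap_cv",
    "global_importance",
    "directionality_summary",
]


# ---------------------------------------------------------------------------
# Path-dependent TreeSHAP for one decision tree (iterative, numba-compiled)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _extend(feat, zero, one, w, m, pz, po, pf):
    """Extend the split path by one element; returns new length m+1."""
    feat[m] = pf
    zero[m] = pz
    one[m] = po
    w[m] = 1.0 if m == 0 else 0.0
    for i in range(m - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / (m + 1)
        w[i] = pz * w[i] * (m - i) / (m + 1)
    return m + 1


@njit(cache=True)
def _unwound_sum(zero, one, w, m, idx):
    """Sum of permutation weights with path element ``idx`` unwound."""
    one_f = one[idx]
    zero_f = zero[idx]
    nxt = w[m - 1]
    total = 0.0
    if one_f != 0.0:
        for j in range(m - 2, -1, -1):
            tmp = nxt * m / ((j + 1) * one_f)
            total += tmp
            nxt = w[j] - tmp * zero_f * (m - 1 - j) / m
    else:
        for j in range(m - 2, -1, -1):
            total += w[j] * m / (zero_f * (m - 1 - j))
    return total


@njit(cache=True)
def _unwind(feat, zero, one, w, m, idx):
    """Remove path element ``idx`` in place; returns new length m-1."""
    one_f = one[idx]
    zero_f = zero[idx]
    nxt = w[m - 1]
    for j in range(m - 2, -1, -1):
        if one_f != 0.0:
            tmp = w[j]
            w[j] = nxt * m / ((j + 1) * one_f)
            nxt = tmp - w[j] * zero_f * (m - 1 - j) / m
        else:
            w[j] = w[j] * m / (zero_f * (m - 1 - j))
    for j in range(idx, m - 1):
        feat[j] = feat[j + 1]
        zero[j] = zero[j + 1]
        one[j] = one[j + 1]
    return m - 1


@njit(cache=True)
def _tree_shap_row(
    x, left, right, feature, threshold, leaf_values, node_weight, max_depth, phi
):
    """Accumulate one tree's Shapley attributions for one row into phi."""
    D = max_depth + 4
    F = max_depth + 8
    st_node = np.empty(F, dtype=np.int64)
    st_m = np.empty(F, dtype=np.int64)
    st_pz = np.empty(F, dtype=np.float64)
    st_po = np.empty(F, dtype=np.float64)
    st_pf = np.empty(F, dtype=np.int64)
    st_feat = np.empty((F, D), dtype=np.int64)
    st_zero = np.empty((F, D), dtype=np.float64)
    st_one = np.empty((F, D), dtype=np.float64)
    st_w = np.empty((F, D), dtype=np.float64)

    feat = np.empty(D, dtype=np.int64)
    zero = np.empty(D, dtype=np.float64)
    one = np.empty(D, dtype=np.float64)
    w = np.empty(D, dtype=np.float64)

    top = 0
    st_node[0] = 0
    st_m[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pf[0] = -1
    top = 1
    n_classes = leaf_values.shape[1]

    while top > 0:
        top -= 1
        node = st_node[top]
        m = st_m[top]
        pz = st_pz[top]
        po = st_po[top]
        pf = st_pf[top]
        for j in range(m):
            feat[j] = st_feat[top, j]
            zero[j] = st_zero[top, j]
            one[j] = st_one[top, j]
            w[j] = st_w[top, j]

        m = _extend(feat, zero, one, w, m, pz, po, pf)

        if left[node] < 0:  # leaf
            for i in range(1, m):
                wsum = _unwound_sum(zero, one, w, m, i)
                scale = wsum * (one[i] - zero[i])
                fi = feat[i]
                for c in range(n_classes):
                    phi[fi, c] += scale * leaf_values[node, c]
        else:
            split = feature[node]
            if x[split] <= threshold[node]:
                hot, cold = left[node], right[node]
            else:
                hot, cold = right[node], left[node]
            wn = node_weight[node]
            hot_zero = node_weight[hot] / wn
            cold_zero = node_weight[cold] / wn
            inc_zero = 1.0
            inc_one = 1.0
            k = -1
            for j in range(1, m):
                if feat[j] == split:
                    k = j
                    break
            if k >= 0:
                inc_zero = zero[k]
                inc_one = one[k]
                m = _unwind(feat, zero, one, w, m, k)
            # push cold then hot (order irrelevant)
            for child, cz, co in ((cold, cold_zero * inc_zero, 0.0),
                                  (hot, hot_zero * inc_zero, inc_one)):
                st_node[top] = child
                st_m[top] = m
                st_pz[top] = cz
                st_po[top] = co
                st_pf[top] = split
                for j in range(m):
                    st_feat[top, j] = feat[j]
                    st_zero[top, j] = zero[j]
                    st_one[top, j] = one[j]
                    st_w[top, j] = w[j]
                top += 1


@njit(cache=True)
def _tree_shap_matrix(
    X, left, right, feature, threshold, leaf_values, node_weight, max_depth
):
    n, d = X.shape
    n_classes = leaf_values.shape[1]
    phi = np.zeros((n, d, n_classes))
    for i in range(n):
        _tree_shap_row(
            X[i], left, right, feature, threshold, leaf_values, node_weight,
            max_depth, phi[i],
        )
    return phi


def _leaf_probabilities(tree) -> np.ndarray:
    """Per-node class probability vectors for a fitted sklearn tree."""
    vals = tree.tree_.value[:, 0, :].astype(np.float64)
    sums = vals.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    out = vals / sums
    # already-normalised values (sklearn >= 1.4) pass through unchanged
    return np.ascontiguousarray(out)


def forest_shap_values(
    model: RandomForestClassifier, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Path-dependent Shapley attributions for a random forest.

    Returns
    -------
    phi : (n_rows, n_features, n_classes)
        Per-feature attributions in probability space; averaging over the
        ensemble mirrors the forest's probability averaging, so for every
        row and class ``base[c] + phi[i, :, c].sum()`` equals
        ``model.predict_proba(X)[i, c]`` up to floating-point error.
    base : (n_classes,)
        Expected predicted probability per class (ensemble mean of the
        trees' root-node class fractions).
    """
    if not hasattr(model, "estimators_"):
        raise TypeError(
            f"model of type {type(model).__name__} has no tree ensemble to explain"
        )
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    n_classes = len(model.classes_)
    phi = np.zeros((len(X), X.shape[1], n_classes))
    base = np.zeros(n_classes)
    for est in model.estimators_:
        t = est.tree_
        leaf_values = _leaf_probabilities(est)
        phi += _tree_shap_matrix(
            X,
            t.children_left.astype(np.int64),
            t.children_right.astype(np.int64),
            t.feature.astype(np.int64),
            t.threshold.astype(np.float64),
            leaf_values,
            t.weighted_n_node_samples.astype(np.float64),
            int(t.max_depth),
        )
        base += leaf_values[0]
    n_trees = len(model.estimators_)
    return phi / n_trees, base / n_trees


# ---------------------------------------------------------------------------
# CV-pooled attributions
# ---------------------------------------------------------------------------


@dataclass
class ShapResult:
    """Held-out attributions pooled across repeats and folds.

    ``values[i, f, c]`` is the attribution of encoded feature ``f`` to
    class ``c`` for pooled row ``i``; ``base_values[i, c]`` the matching
    base value; ``feature_values`` the encoded feature matrix the model
    saw.  Each participant appears once per repeat (simple
    concatenation of held-out partitions).
    """

    values: np.ndarray
    base_values: np.ndarray
    feature_values: np.ndarray
    row_ids: np.ndarray
    repeat: np.ndarray
    fold: np.ndarray
    feature_names: list[str]
    classes: list[str]

    def class_index(self, class_label: str) -> int:
        try:
            return self.classes.index(str(class_label))
        except ValueError:
            raise KeyError(f"unknown class {class_label!r}; have {self.classes}")

    def predicted_probability(self) -> np.ndarray:
        """base + sum of attributions, per row and class (additivity check)."""
        return self.base_values + self.values.sum(axis=1)


def compute_shap_cv(fold_results: Sequence[FoldResult]) -> ShapResult:
    """Explain every fold's held-out rows and pool the attributions.

    Feature columns are aligned on the union of the folds' encoded
    feature names (a level absent from one fold's training data simply
    contributes zero attributions there); class sets must agree across
    folds.
    """
    if not fold_results:
        raise ValueError("no fold results to explain")
    classes = [str(c) for c in fold_results[0].model.classes_]
    union: list[str] = []
    for fr in fold_results:
        if [str(c) for c in fr.model.classes_] != classes:
            raise ValueError("fold models disagree on the class set")
        for name in fr.feature_names:
            if name not in union:
                union.append(name)

    vals, bases, feats, rows, reps, folds = [], [], [], [], [], []
    for fr in fold_results:
        phi, base = forest_shap_values(fr.model, fr.X_test)
        n = len(fr.X_test)
        col = {name: j for j, name in enumerate(fr.feature_names)}
        phi_u = np.zeros((n, len(union), len(classes)))
        x_u = np.zeros((n, len(union)))
        for j, name in enumerate(union):
            if name in col:
                phi_u[:, j, :] = phi[:, col[name], :]
                x_u[:, j] = fr.X_test[:, col[name]]
        vals.append(phi_u)
        bases.append(np.tile(base, (n, 1)))
        feats.append(x_u)
        rows.append(np.asarray(fr.test_ids))
        reps.append(np.full(n, fr.repeat))
        folds.append(np.full(n, fr.fold))
    return ShapResult(
        values=np.concatenate(vals),
        base_values=np.concatenate(bases),
        feature_values=np.concatenate(feats),
        row_ids=np.concatenate(rows),
        repeat=np.concatenate(reps),
        fold=np.concatenate(folds),
        feature_names=union,
        classes=classes,
    )


def global_importance(
    shap_result: ShapResult,
    class_label: str,
    top_m: int = 10,
    aggregate_levels: bool = False,
) -> pd.DataFrame:
    """Mean absolute attribution per feature for one class, ranked.

    With ``aggregate_levels=True`` one-hot indicator columns are summed
    back to their parent variable (``education.secondary`` →
    ``education``) before ranking; by default levels are reported
    individually.  Ties keep the stable feature order.
    """
    if len(shap_result.values) == 0:
        raise ValueError("empty attribution pool")
    c = shap_result.class_index(class_label)
    abs_vals = np.abs(shap_result.values[:, :, c])
    names = list(shap_result.feature_names)
    if aggregate_levels:
        parents: dict[str, np.ndarray] = {}
        for j, name in enumerate(names):
            parent = name.rsplit(".", 1)[0] if "." in name else name
            parents.setdefault(parent, np.zeros(len(abs_vals)))
            parents[parent] += shap_result.values[:, j, c]
        names = list(parents)
        abs_vals = np.abs(np.column_stack([parents[p] for p in names]))
    importance = abs_vals.mean(axis=0)
    order = np.argsort(-importance, kind="stable")
    table = pd.DataFrame(
        {
            "feature": [names[j] for j in order],
            "mean_abs_shap": importance[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return table.head(top_m) if top_m is not None else table


def directionality_summary(
    shap_result: ShapResult,
    feature: str,
    class_label: str,
) -> tuple[pd.DataFrame, float]:
    """Beeswarm-style local data for one feature and class.

    Returns per-row (feature value, attribution) pairs and a
    sign-concordance score: for a continuous feature, the fraction of
    rows where the attribution's sign matches the sign of (value -
    pooled median); for a 0/1 indicator, the fraction of indicator-1
    rows with positive attribution.  NaN when undefined (constant
    feature or no informative rows).
    """
    if feature not in shap_result.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = shap_result.feature_names.index(feature)
    c = shap_result.class_index(class_label)
    x = shap_result.feature_values[:, j]
    phi = shap_result.values[:, j, c]
    table = pd.DataFrame({"value": x, "shap": phi})
    if np.ptp(x) == 0:
        return table, float("nan")
    is_indicator = set(np.unique(x)) <= {0.0, 1.0}
    if is_indicator:
        on = x == 1.0
        if not on.any():
            return table, float("nan")
        score = float(np.mean(phi[on] > 0))
    else:
        centred = x - np.median(x)
        keep = (centred != 0) & (phi != 0)
        if not keep.any():
            return table, float("nan")
        score = float(np.mean(np.sign(phi[keep]) == np.sign(centred[keep])))
    return table, score
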