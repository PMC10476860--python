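"""Isolation Forest, implemented from first principles.

The forest serves two roles in the pipeline: one-class screening of CRC
against negative controls with leave-one-out cross-validation (few cases,
so no biomarker selection is possible), and the construction of a
*representative* held-out test subset for the marker-panel model (outliers
of a class are excluded from test eligibility, then the test samples are
drawn stratified across anomaly-score quartiles).

An isolation tree recursively splits a uniform subsample on a uniformly
chosen feature at a uniform point inside the node's observed range; anomalies
isolate in few splits.  With ``h(x)`` the path length of a query and
``c(n) = 2 H(n-1) - 2 (n-1)/n`` the expected path length of an unsuccessful
BST search over ``n`` points, the anomaly score is

    s(x) = 2 ** (-E[h(x)] / c(n_sub))

so a point with average path length equal to ``c(n_sub)`` scores exactly 0.5
and scores approach 1 for points isolated near the root.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .evaluation import ClassifierReport, evaluate

_EULER_GAMMA = 0.5772156649015329


def harmonic(n: int) -> float:
    """H(n), exactly for n <= 100, via ln(n) + Euler–Mascheroni above."""
    if n <= 0:
        return 0.0
    if n <= 100:
        return float(sum(1.0 / k for k in range(1, n + 1)))
    return math.log(n) + _EULER_GAMMA + 1.0 / (2 * n) - 1.0 / (12 * n * n)


def average_path_length(n: int) -> float:
    """c(n): expected unsuccessful-search path length in a BST of n points."""
    if n <= 1:
        return 0.0
    return 2.0 * harmonic(n - 1) - 2.0 * (n - 1) / n


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    size: int = 0  # leaf only: samples that terminated here

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class IsolationTree:
    root: _Node
    n_sub: int

    def path_length(self, x: np.ndarray) -> float:
        node, depth = self.root, 0
        while not node.is_leaf:
            node = node.left if x[node.feature] < node.threshold else node.right
            depth += 1
        return depth + average_path_length(node.size)


@dataclass
class IForestModel:
    trees: list[IsolationTree]
    n_sub: int
    n_features: int
    rng_seed: int


@dataclass
class AnomalyScore:
    value: float
    expected_path_length: float
    normalizer: float


def _grow(X: np.ndarray, idx: np.ndarray, depth: int, max_depth: int, rng) -> _Node:
    n = idx.size
    if n <= 1 or depth >= max_depth:
        return _Node(size=n)
    sub = X[idx]
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    splittable = np.flatnonzero(hi > lo)
    if splittable.size == 0:  # all duplicates
        return _Node(size=n)
    f = int(rng.choice(splittable))
    t = float(rng.uniform(lo[f], hi[f]))
    left_mask = sub[:, f] < t
    # uniform draw can hit the max exactly; nudge so both children are nonempty
    if not left_mask.any() or left_mask.all():
        return _Node(size=n)
    node = _Node(feature=f, threshold=t)
    node.left = _grow(X, idx[left_mask], depth + 1, max_depth, rng)
    node.right = _grow(X, idx[~left_mask], depth + 1, max_depth, rng)
    return node


def fit_iforest(
    X: np.ndarray, n_trees: int = 500, n_sub: int | None = None, seed: int = 0
) -> IForestModel:
    """Fit an isolation forest on complete data.

    Each tree grows on an independent uniform subsample without replacement
    (default size min(256, n)); growth stops at singletons, duplicate
    points, or the depth cap ceil(log2(n_sub)).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("isolation forest requires complete data")
    n = X.shape[0]
    if n_sub is None:
        n_sub = min(256, n)
    if n_sub > n:
        warnings.warn(f"n_sub={n_sub} > n={n}; lowering to n")
        n_sub = n
    if n_trees < 1 or n_sub < 2:
        raise ValueError("need n_trees >= 1 and n_sub >= 2")
    rng = np.random.default_rng(seed)
    max_depth = int(math.ceil(math.log2(n_sub)))
    trees = []
    for _ in range(n_trees):
        idx = rng.choice(n, size=n_sub, replace=False)
        trees.append(IsolationTree(_grow(X, idx, 0, max_depth, rng), n_sub))
    return IForestModel(trees=trees, n_sub=n_sub, n_features=X.shape[1], rng_seed=seed)


def score(m: IForestModel, x: np.ndarray) -> AnomalyScore:
    """Anomaly score of one query point, in (0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != m.n_features:
        raise ValueError(f"query has {x.size} features, model expects {m.n_features}")
    eh = float(np.mean([t.path_length(x) for t in m.trees]))
    c = average_path_length(m.n_sub)
    return AnomalyScore(value=2.0 ** (-eh / c), expected_path_length=eh, normalizer=c)


def score_samples(m: IForestModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.array([score(m, row).value for row in X])


def one_class_loo(
    controls: np.ndarray,
    cases: np.ndarray,
    n_trees: int = 500,
    n_sub: int | None = None,
    seed: int = 0,
    spec_target: float = 0.70,
) -> ClassifierReport:
    """One-class screening: train on controls, score cases as anomalies.

    Each control is scored by a forest fit on the other controls
    (leave-one-out); all cases are scored by a forest fit on every control.
    The pooled scores give a ROC; the operating threshold fixes specificity
    at ``spec_target`` (closest from above) and sensitivity is read off.
    """
    controls = np.asarray(controls, dtype=float)
    cases = np.asarray(cases, dtype=float)
    n_ctrl = controls.shape[0]
    if n_ctrl < 10:
        raise ValueError("need at least 10 controls for leave-one-out screening")
    if n_sub is not None and n_sub > n_ctrl - 1:
        warnings.warn("n_sub exceeds leave-one-out control count; lowering")
        n_sub = n_ctrl - 1
    ss = np.random.SeedSequence(seed)
    loo_seeds = ss.generate_state(n_ctrl + 1) % (2**31)
    ctrl_scores = np.empty(n_ctrl)
    for i in range(n_ctrl):
        rest = np.delete(controls, i, axis=0)
        m = fit_iforest(rest, n_trees=n_trees, n_sub=n_sub, seed=int(loo_seeds[i]))
        ctrl_scores[i] = score(m, controls[i]).value
    m_all = fit_iforest(controls, n_trees=n_trees, n_sub=n_sub, seed=int(loo_seeds[-1]))
    case_scores = score_samples(m_all, cases)
    y = np.concatenate([np.zeros(n_ctrl, dtype=int), np.ones(cases.shape[0], dtype=int)])
    s = np.concatenate([ctrl_scores, case_scores])
    return evaluate(s, y, spec_target=spec_target)


def representative_split(
    t: FeatureTable,
    labels: "np.ndarray | list",
    n_test_per_class: int,
    seed: int = 0,
    n_trees: int = 200,
    outlier_quantile: float = 0.90,
) -> tuple[list, list]:
    """Split into training and a *representative* held-out test set.

    Per class: fit an isolation forest on the class alone, rank its samples
    by anomaly score, drop the top decile (outliers) from test eligibility,
    then draw test samples stratified across the anomaly-score quartiles of
    the remainder so the test set spans typical members of the class.  All
    non-test samples (outliers included) stay in training.

    Returns (train sample ids, test sample ids).
    """
    labels = np.asarray(labels)
    ss = np.random.SeedSequence(seed)
    test_ids: list = []
    X_all = t.values.to_numpy(dtype=float)
    ids = np.asarray(t.values.index)
    for ci, cls in enumerate(pd.unique(labels)):
        rows = np.flatnonzero(labels == cls)
        if rows.size <= n_test_per_class:
            raise ValueError(f"class {cls!r} too small to withhold {n_test_per_class}")
        child = np.random.SeedSequence([seed, ci])
        fseed = int(child.generate_state(1)[0] % (2**31))
        m = fit_iforest(X_all[rows], n_trees=n_trees, seed=fseed)
        scores = score_samples(m, X_all[rows])
        cutoff = np.quantile(scores, outlier_quantile)
        eligible = rows[scores <= cutoff]
        elig_scores = scores[scores <= cutoff]
        if eligible.size < n_test_per_class:
            raise ValueError(f"class {cls!r} too small after outlier exclusion")
        # stratify across anomaly-score quartiles of the eligible remainder
        order = np.argsort(elig_scores, kind="stable")
        strata = np.array_split(order, 4)
        rng = np.random.default_rng(child.spawn(1)[0])
        base, extra = divmod(n_test_per_class, 4)
        take_counts = [base + (1 if k < extra else 0) for k in range(4)]
        chosen: list[int] = []
        for stratum, k in zip(strata, take_counts):
            k = min(k, stratum.size)
            chosen.extend(rng.choice(stratum, size=k, replace=False))
        # top up from unchosen eligible samples if any stratum ran short
        short = n_test_per_class - len(chosen)
        if short > 0:
            rest = np.setdiff1d(order, np.array(chosen, dtype=int))
            chosen.extend(rng.choice(rest, size=short, replace=False))
        test_ids.extend(ids[eligible[np.asarray(chosen, dtype=int)]])
    test_set = set(test_ids)
    train_ids = [i for i in ids if i not in test_set]
    return train_ids, sorted(test_ids, key=list(ids).index)
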