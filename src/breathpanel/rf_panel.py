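"""Random-Forest marker-panel discovery (advanced adenoma vs control).

Workflow: an iterative internal validation procedure refits many
independent forests and averages each feature's out-of-bag (OOB)
permutation importance; a compact marker panel is chosen from the ranking;
OOB co-leaf proximities are embedded by principal coordinate analysis for
visualization; performance is reported as ROC / precision-recall curves,
specificity-anchored sensitivity and PPV.  The selected panel can be
transferred to other contrasts (CRC vs control, CRC+AA vs control) by
refitting a forest restricted to the panel's features.

The forest itself is scikit-learn's; OOB bookkeeping, permutation
importance, proximities and the ordination are computed here from the
per-tree bootstrap membership and leaf assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import ClassifierReport, evaluate


@dataclass
class RFModel:
    """A fitted forest plus the OOB bookkeeping the downstream steps need."""

    forest: RandomForestClassifier
    X: np.ndarray  # training matrix, float32
    y: np.ndarray  # encoded labels (ints into classes_)
    oob_mask: np.ndarray  # (n_trees, n_samples) True where the sample is OOB
    classes_: np.ndarray
    feature_names: list[str] | None = None
    rng_seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)


@dataclass
class ImportanceRanking:
    """Mean OOB permutation importance per feature over repeated forests.

    ``signs`` give each feature's direction of class association: positive
    means the feature is higher (on the modelling scale) in the positive
    class — for the AA-vs-control contrast, higher in advanced adenomas.
    """

    mean_importance: pd.Series
    draws: pd.DataFrame  # iterations x features
    signs: pd.Series

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[0]

    def ranked_features(self) -> list:
        return list(self.mean_importance.sort_values(ascending=False, kind="stable").index)


@dataclass
class MarkerPanel:
    """Ordered discriminatory features with signed mean importance."""

    features: list
    signed_importance: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise ValueError("empty marker panel")
        mags = self.signed_importance.loc[self.features].abs().to_numpy()
        if np.any(np.diff(mags) > 1e-12):
            raise ValueError("panel must be ordered by |importance| descending")

    def __len__(self) -> int:
        return len(self.features)

    def truncate(self, k: int) -> "MarkerPanel":
        return MarkerPanel(self.features[:k], self.signed_importance, dict(self.provenance))


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # n x k, ordered by eigenvalue descending
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues; sums to <= 1
    sample_ids: list | None = None


def fit_rf(
    X: np.ndarray, y: np.ndarray, n_trees: int = 1000, seed: int = 0, feature_names=None
) -> RFModel:
    """Bagged randomized trees with sqrt-feature subsetting and OOB bookkeeping.

    Guarantees every sample is out-of-bag in at least one tree (the forest
    is regrown with more trees in the unlikely event one is not).
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("random forest requires a complete matrix")
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    n = X.shape[0]
    trees = n_trees
    for _ in range(5):
        forest = RandomForestClassifier(
            n_estimators=trees,
            max_features="sqrt",
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        ).fit(X, y_enc)
        oob_mask = np.ones((trees, n), dtype=bool)
        for t, sampled in enumerate(forest.estimators_samples_):
            oob_mask[t, sampled] = False
        if oob_mask.any(axis=0).all():
            break
        trees *= 2
    else:
        raise RuntimeError("could not ensure OOB coverage for every sample")
    return RFModel(
        forest=forest,
        X=X,
        y=y_enc,
        oob_mask=oob_mask,
        classes_=classes,
        feature_names=list(feature_names) if feature_names is not None else None,
        rng_seed=seed,
    )


def _tree_pred(tree, X32: np.ndarray) -> np.ndarray:
    """Per-tree predicted class indices without sklearn's validation overhead."""
    out = tree.tree_.predict(X32)
    if out.ndim == 3:
        out = out[:, 0, :]
    return out.argmax(axis=1)


def oob_votes(m: RFModel) -> np.ndarray:
    """OOB vote counts, samples x classes."""
    n, k = m.X.shape[0], m.classes_.size
    votes = np.zeros((n, k), dtype=np.int32)
    for t, tree in enumerate(m.forest.estimators_):
        rows = np.flatnonzero(m.oob_mask[t])
        pred = _tree_pred(tree, m.X[rows])
        np.add.at(votes, (rows, pred), 1)
    return votes


def oob_predictions(m: RFModel) -> np.ndarray:
    """OOB majority-vote class labels (original label space)."""
    return m.classes_[oob_votes(m).argmax(axis=1)]


def oob_scores(m: RFModel, positive_class=None) -> np.ndarray:
    """OOB vote fraction for the positive class (default: last class)."""
    votes = oob_votes(m)
    ci = m.classes_.size - 1 if positive_class is None else int(np.flatnonzero(m.classes_ == positive_class)[0])
    tot = votes.sum(axis=1)
    return votes[:, ci] / np.maximum(tot, 1)


def _oob_permutation_importance(m: RFModel, rng: np.random.Generator) -> np.ndarray:
    """Breiman-style importance: per-tree OOB accuracy drop when one
    feature's OOB values are permuted, averaged over trees."""
    n, p = m.X.shape
    n_trees = m.n_trees
    drops = np.zeros(p)
    counts = np.zeros(p)
    for t, tree in enumerate(m.forest.estimators_):
        rows = np.flatnonzero(m.oob_mask[t])
        Xsub = np.ascontiguousarray(m.X[rows])
        ysub = m.y[rows]
        base_acc = float(np.mean(_tree_pred(tree, Xsub) == ysub))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            orig = Xsub[:, j].copy()
            Xsub[:, j] = orig[rng.permutation(rows.size)]
            acc = float(np.mean(_tree_pred(tree, Xsub) == ysub))
            Xsub[:, j] = orig
            drops[j] += base_acc - acc
            counts[j] += 1
    # features never used by any tree carry zero importance
    return drops / n_trees


def iterative_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 1000,
    trees_per_iter: int = 1000,
    seed: int = 0,
    feature_names=None,
    positive_class=None,
) -> ImportanceRanking:
    """Iterative internal validation of variable importance.

    Fits ``n_iter`` independent forests (fresh bootstrap seeds) of
    ``trees_per_iter`` trees each and averages per-feature OOB permutation
    importance across them.  Signs come from the difference of class means
    of each (scaled) feature: positive = higher in the positive class.
    """
    if n_iter < 2:
        raise ValueError("need at least 2 iterations to estimate dispersion")
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    p = X.shape[1]
    if feature_names is None:
        feature_names = list(range(p))
    feature_names = pd.Index(feature_names)

    classes = np.unique(y)
    pos = classes[-1] if positive_class is None else positive_class
    neg_mask, pos_mask = y != pos, y == pos
    diff = X[pos_mask].mean(axis=0) - X[neg_mask].mean(axis=0)
    signs = pd.Series(np.where(diff >= 0, 1, -1).astype(int), index=feature_names)

    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.generate_state(n_iter) % (2**31)
    draws = np.empty((n_iter, p))
    for it in range(n_iter):
        m = fit_rf(X, y, n_trees=trees_per_iter, seed=int(fit_seeds[it]))
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF, it]))
        draws[it] = _oob_permutation_importance(m, rng)
    draws_df = pd.DataFrame(draws, columns=feature_names)
    return ImportanceRanking(
        mean_importance=draws_df.mean(axis=0), draws=draws_df, signs=signs
    )


def _oob_youden(m: RFModel) -> tuple[float, float]:
    """(Youden index, its binomial standard error) from OOB majority votes."""
    pred = oob_predictions(m)
    y = m.classes_[m.y]
    pos = m.classes_[-1]
    pos_mask = y == pos
    sens = float(np.mean(pred[pos_mask] == pos))
    spec = float(np.mean(pred[~pos_mask] != pos))
    n_pos, n_neg = int(pos_mask.sum()), int((~pos_mask).sum())
    se = float(np.sqrt(sens * (1 - sens) / n_pos + spec * (1 - spec) / n_neg))
    return sens + spec - 1.0, se


def select_panel(
    r: ImportanceRanking,
    X: np.ndarray,
    y: np.ndarray,
    k_grid=(3, 5, 10, 15, 20),
    n_trees: int = 500,
    seed: int = 0,
    force_k: int | None = None,
) -> MarkerPanel:
    """Choose a marker panel from the importance ranking.

    For each candidate size ``k`` a forest is refit on the top-``k``
    features and its OOB Youden index recorded; the smallest ``k`` within
    one standard error of the best is returned (``force_k`` pins the size
    instead, e.g. 10 to mirror a fixed-panel protocol).  The panel carries
    signed importances (sign = direction of class association).
    """
    ranked = r.ranked_features()
    signed = r.mean_importance * r.signs
    X = np.asarray(X, dtype=np.float32)
    names = list(r.mean_importance.index)
    col_of = {f: i for i, f in enumerate(names)}

    def _panel(features: list, provenance: dict) -> MarkerPanel:
        ordered = sorted(features, key=lambda f: -abs(signed[f]))
        return MarkerPanel(ordered, signed, provenance)

    if force_k is not None:
        return _panel(ranked[:force_k], {"rule": f"forced k={force_k}", "seed": seed})

    k_grid = sorted({min(k, len(ranked)) for k in k_grid})
    if not k_grid:
        raise ValueError("empty k_grid")
    results = []
    for ki, k in enumerate(k_grid):
        cols = [col_of[f] for f in ranked[:k]]
        m = fit_rf(X[:, cols], y, n_trees=n_trees, seed=int(np.random.SeedSequence([seed, ki]).generate_state(1)[0] % (2**31)))
        results.append(_oob_youden(m))
    youdens = np.array([j for j, _ in results])
    best = int(np.argmax(youdens))
    se_best = results[best][1]
    chosen_k = next(k for k, j in zip(k_grid, youdens) if j >= youdens[best] - se_best)
    return _panel(
        ranked[:chosen_k], {"rule": "one-SE OOB Youden", "k_grid": list(k_grid), "seed": seed}
    )


def oob_proximity(m: RFModel) -> tuple[np.ndarray, int]:
    """OOB co-leaf proximity matrix of the training samples.

    Entry (i, j) is the fraction of trees, among those where both samples
    are OOB, in which the two land in the same terminal leaf.  Pairs never
    jointly OOB get 0; their count is returned alongside (a warning is
    emitted when it is nonzero).  Diagonal forced to 1.
    """
    n = m.X.shape[0]
    co = np.zeros((n, n))
    both = np.zeros((n, n))
    leaves = m.forest.apply(m.X)  # n x n_trees
    for t in range(m.n_trees):
        rows = np.flatnonzero(m.oob_mask[t])
        lv = leaves[rows, t]
        same = lv[:, None] == lv[None, :]
        co[np.ix_(rows, rows)] += same
        both[np.ix_(rows, rows)] += 1
    never = int(np.sum((both == 0) & ~np.eye(n, dtype=bool)) // 2)
    if never:
        warnings.warn(f"{never} sample pair(s) never jointly OOB; proximity set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        prox = np.where(both > 0, co / np.maximum(both, 1), 0.0)
    np.fill_diagonal(prox, 1.0)
    return prox, never


def pcoa(p: np.ndarray, sample_ids=None) -> PCoAResult:
    """Classical MDS of the proximity-derived distance d = sqrt(1 - proximity).

    Double-centers -1/2 * J D^2 J, eigendecomposes, and returns coordinates
    scaled by the square roots of the positive eigenvalues; explained-
    variance fractions are taken over positive eigenvalues only.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    if p.shape != (n, n) or not np.allclose(p, p.T, atol=1e-10):
        raise ValueError("proximity matrix must be square symmetric")
    D2 = np.clip(1.0 - p, 0.0, None)  # squared distances: d^2 = 1 - proximity
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval[0]) if eigval.size else 0.0)
    if not pos.any():
        warnings.warn("degenerate embedding: no positive eigenvalues")
        return PCoAResult(np.zeros((n, 1)), eigval, np.array([0.0]), sample_ids)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    frac = eigval[pos] / eigval[pos].sum()
    return PCoAResult(coords, eigval, frac, sample_ids)


def predict_scores(m: RFModel, X_new: np.ndarray, positive_class=None) -> np.ndarray:
    """Positive-class probability for new samples."""
    ci = m.classes_.size - 1 if positive_class is None else int(np.flatnonzero(m.classes_ == positive_class)[0])
    return m.forest.predict_proba(np.asarray(X_new, dtype=np.float32))[:, ci]


def transfer_panel(
    panel: MarkerPanel,
    X_new: pd.DataFrame,
    y_new: np.ndarray,
    spec_target: float = 0.70,
    n_trees: int = 1000,
    seed: int = 0,
) -> ClassifierReport:
    """Refit a forest restricted to the panel's features on a new contrast.

    ``X_new`` must be a DataFrame containing every panel feature as a
    column; evaluation uses OOB positive-class vote fractions with the
    specificity-anchored operating point.
    """
    missing = [f for f in panel.features if f not in X_new.columns]
    if missing:
        raise ValueError(f"panel features absent from new data: {missing}")
    Xp = X_new[list(panel.features)].to_numpy(dtype=np.float32)
    m = fit_rf(Xp, y_new, n_trees=n_trees, seed=seed, feature_names=list(panel.features))
    scores = oob_scores(m)
    y_bin = (np.asarray(y_new) == m.classes_[-1]).astype(int)
    return evaluate(scores, y_bin, spec_target=spec_target)
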