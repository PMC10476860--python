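"""Hierarchical midlevel-fusion 3-class model (AA vs NAA vs control).

Two binary submodels are built first: Model A separates advanced adenomas
from everything else, and Model B separates non-advanced adenomas from
controls (fitted only on those two classes).  Each submodel is summarized
by its samples' scores on the first principal coordinate of the OOB-
proximity PCoA; the AA-vs-control marker-panel model contributes a third
score.  The three first-PCo score columns are fused (midlevel fusion) and
a final random forest on the fused 3-column matrix yields the 3-class
prediction, assessed by weighted accuracy (mean of per-class recalls;
1/3 under random assignment).

Samples a submodel never saw (e.g. AA samples for Model B) are completed by
out-of-sample PCoA projection: their proximity to the training samples is
computed over *all* trees (OOB proximity is undefined for unseen samples)
and projected onto the stored eigenvector via the classical out-of-sample
formula, which introduces a mild train/new score-scale mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rf_panel import RFModel, PCoAResult, fit_rf, oob_proximity, pcoa


@dataclass
class Submodel:
    """A fitted binary submodel with its proximity ordination."""

    model: RFModel
    pcoa: PCoAResult
    train_ids: list
    proximity: np.ndarray
    submodel_id: str

    @property
    def scores(self) -> pd.Series:
        """First-PCo score per training sample."""
        return pd.Series(self.pcoa.coordinates[:, 0], index=self.train_ids, name=self.submodel_id)


@dataclass
class ThreeClassReport:
    confusion: pd.DataFrame  # rows true, cols predicted
    per_class_recall: pd.Series
    weighted_accuracy: float

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "per_class_recall": self.per_class_recall.to_dict(),
            "weighted_accuracy": self.weighted_accuracy,
        }


def fit_submodel(
    X: pd.DataFrame, y_binary: np.ndarray, n_trees: int = 1000, seed: int = 0, submodel_id: str = ""
) -> Submodel:
    """Fit one binary submodel and its first-PCo score extraction.

    ``X`` holds only the samples this submodel is allowed to see (Model B,
    for instance, must be fitted on NAA and control samples exclusively).
    """
    m = fit_rf(X.to_numpy(dtype=np.float32), y_binary, n_trees=n_trees, seed=seed,
               feature_names=list(X.columns))
    prox, _ = oob_proximity(m)
    emb = pcoa(prox, sample_ids=list(X.index))
    return Submodel(model=m, pcoa=emb, train_ids=list(X.index), proximity=prox,
                    submodel_id=submodel_id)


def _all_trees_proximity(sub: Submodel, X_new: np.ndarray) -> np.ndarray:
    """Proximity of new samples to the training samples over all trees."""
    train_leaves = sub.model.forest.apply(sub.model.X)  # n_train x n_trees
    new_leaves = sub.model.forest.apply(np.asarray(X_new, dtype=np.float32))
    n_trees = train_leaves.shape[1]
    return (new_leaves[:, None, :] == train_leaves[None, :, :]).sum(axis=2) / n_trees


def project_pco(sub: Submodel, X_new: pd.DataFrame | np.ndarray, component: int = 0) -> pd.Series:
    """Out-of-sample first-PCo score for new samples.

    Uses the classical projection: with training squared distances
    ``D2`` (row means ``r``), eigenvector ``v`` and eigenvalue ``l`` of the
    double-centered matrix, a new point with squared distances ``d2`` to the
    training samples scores ``-(v @ (d2 - r)) / (2 sqrt(l))``.
    """
    if isinstance(X_new, pd.DataFrame):
        ids = list(X_new.index)
        Xn = X_new.to_numpy(dtype=np.float32)
    else:
        Xn = np.asarray(X_new, dtype=np.float32)
        ids = list(range(Xn.shape[0]))
    if Xn.shape[1] != sub.model.X.shape[1]:
        raise ValueError("new samples have a different feature count than the submodel")
    prox_new = _all_trees_proximity(sub, Xn)
    d2_new = np.clip(1.0 - prox_new, 0.0, None)  # (n_new, n_train)
    D2_train = np.clip(1.0 - sub.proximity, 0.0, None)
    r = D2_train.mean(axis=1)
    lam = sub.pcoa.eigenvalues[component]
    # recover the unit eigenvector: coordinates = v * sqrt(lam)
    v = sub.pcoa.coordinates[:, component] / np.sqrt(lam)
    scores = -0.5 * (d2_new - r[None, :]) @ v / np.sqrt(lam)
    return pd.Series(scores, index=ids, name=sub.submodel_id)


def submodel_scores_for(sub: Submodel, table_values: pd.DataFrame) -> pd.Series:
    """First-PCo score for every sample: training score where available,
    out-of-sample projection otherwise."""
    train = sub.scores
    missing = table_values.index.difference(train.index)
    parts = [train.reindex(table_values.index.intersection(train.index))]
    if len(missing):
        parts.append(project_pco(sub, table_values.loc[missing]))
    return pd.concat(parts).reindex(table_values.index)


def fuse(scores_A: pd.Series, scores_B: pd.Series, scores_M2: pd.Series) -> pd.DataFrame:
    """Midlevel fusion: the three first-PCo score columns, order (A, B, Model2)."""
    fused = pd.concat(
        [scores_A.rename("A"), scores_B.rename("B"), scores_M2.rename("Model2")], axis=1
    )
    if fused.isna().any().any():
        bad = [
            f"{sample}/{col}"
            for col in fused.columns
            for sample in fused.index[fused[col].isna()]
        ]
        raise ValueError(f"missing submodel scores for: {bad}")
    return fused


def weighted_accuracy(confusion: pd.DataFrame | np.ndarray) -> float:
    """Mean of per-class recalls (balanced accuracy) of a 3x3 confusion matrix."""
    C = confusion.to_numpy() if isinstance(confusion, pd.DataFrame) else np.asarray(confusion)
    if (C < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    row_sums = C.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("every true class needs at least one sample")
    return float(np.mean(np.diag(C) / row_sums))


def fit_final(
    fused: pd.DataFrame,
    y_3class: pd.Series,
    n_trees: int = 1000,
    seed: int = 0,
    validation_ids=None,
) -> tuple[RFModel, ThreeClassReport]:
    """Final 3-class forest on the fused scores; report on internal validation.

    When ``validation_ids`` is given the forest trains on the remaining
    samples and the report reflects the validation predictions; otherwise
    OOB predictions on the full fused matrix are reported.  Either way the
    report is internal — the procedure has no independent test set.
    """
    classes = sorted(set(y_3class))
    if not set(y_3class) <= {"AA", "NAA", "control"} or len(classes) != 3:
        raise ValueError("final model expects exactly the classes AA, NAA, control")
    if validation_ids is not None:
        train_idx = fused.index.difference(validation_ids)
        m = fit_rf(
            fused.loc[train_idx].to_numpy(dtype=np.float32),
            y_3class.loc[train_idx].to_numpy(),
            n_trees=n_trees,
            seed=seed,
            feature_names=list(fused.columns),
        )
        pred = m.classes_[
            m.forest.predict_proba(fused.loc[validation_ids].to_numpy(dtype=np.float32)).argmax(axis=1)
        ]
        truth = y_3class.loc[validation_ids].to_numpy()
    else:
        from .rf_panel import oob_predictions

        m = fit_rf(
            fused.to_numpy(dtype=np.float32),
            y_3class.to_numpy(),
            n_trees=n_trees,
            seed=seed,
            feature_names=list(fused.columns),
        )
        pred = oob_predictions(m)
        truth = y_3class.to_numpy()

    C = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(truth, pred):
        C.loc[t, p] += 1
    recalls = pd.Series(np.diag(C) / C.sum(axis=1).to_numpy(), index=classes)
    report = ThreeClassReport(
        confusion=C, per_class_recall=recalls, weighted_accuracy=weighted_accuracy(C)
    )
    return m, report
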