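"""Diagnostic figures: ROC / precision-recall curves and PCoA score plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import ClassifierReport
from .rf_panel import PCoAResult


def plot_roc(report: ClassifierReport, path: str | Path, title: str = "ROC") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr, tpr = report.roc_points[:, 0], report.roc_points[:, 1]
    ax.plot(fpr, tpr, lw=1.5, label=f"AUC = {report.auc_roc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set(xlabel="1 - specificity", ylabel="sensitivity", title=title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pr(report: ClassifierReport, path: str | Path, title: str = "Precision-recall") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    rec, prec = report.pr_points[:, 0], report.pr_points[:, 1]
    ax.plot(rec, prec, lw=1.5, label=f"AUC = {report.auc_pr:.3f}")
    ax.set(xlabel="recall", ylabel="precision", title=title, ylim=(0, 1.02))
    ax.legend(loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pcoa(
    result: PCoAResult, labels, path: str | Path, title: str = "PCoA of OOB proximities"
) -> None:
    labels = np.asarray(labels)
    coords = result.coordinates
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for cls in np.unique(labels):
        rows = labels == cls
        ax.scatter(coords[rows, 0], coords[rows, 1] if coords.shape[1] > 1 else np.zeros(rows.sum()),
                   s=18, alpha=0.75, label=str(cls))
    fx, fy = result.proportion_explained[:2] * 100 if result.proportion_explained.size > 1 else (
        result.proportion_explained[0] * 100, 0.0)
    ax.set(xlabel=f"PCo1 ({fx:.1f}%)", ylabel=f"PCo2 ({fy:.1f}%)", title=title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
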