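"""Instrumental batch-effect removal.

Implements parametric / nonparametric empirical-Bayes location-scale batch
correction (the ComBat model) and a simple two-step surrogate-variable
analysis (residual SVD with a permutation-based choice of the number of
hidden factors).  Biological class labels are included as protected
covariates by default so correction cannot erase class signal.

The batch model for feature *g*, sample *i* in batch *b* is::

    Y_gi = alpha_g + X_i beta_g + gamma_bg + delta_bg * eps_gi

Per-batch location ``gamma`` and scale ``delta^2`` estimates are shrunk
toward common priors — normal for ``gamma``, inverse-gamma for ``delta^2``
(parametric mode) or via Monte-Carlo posterior weighting over the other
features' estimates (nonparametric mode) — then removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable


@dataclass
class BatchDesign:
    """Per-sample batch labels plus covariates to protect during correction.

    ``covariates`` is an n x k matrix (DataFrame) of biological terms whose
    signal must survive correction — by default the workflow passes class
    indicator columns.  Every batch needs at least two samples, and the
    covariates may not be perfectly confounded with batch.
    """

    batch: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.batch.value_counts()
        if (counts < 2).any():
            small = list(counts[counts < 2].index)
            raise ValueError(f"batches with fewer than 2 samples: {small}")
        if self.covariates is not None:
            if not self.covariates.index.equals(self.batch.index):
                raise ValueError("covariates and batch labels index mismatch")
            X = np.column_stack(
                [pd.get_dummies(self.batch, dtype=float).to_numpy(), self.covariates.to_numpy(float)]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("covariates are confounded with batch (rank-deficient design)")

    @property
    def n_batches(self) -> int:
        return self.batch.nunique()


def class_covariates(t: FeatureTable) -> pd.DataFrame:
    """One-hot class indicators (first level dropped) for use as protected covariates."""
    return pd.get_dummies(t.classes, drop_first=True, dtype=float)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _it_sol(Z_b, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch's gamma*, delta2* (parametric)."""
    n = (~np.isnan(Z_b)).sum(axis=0).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = np.nansum((Z_b - g_new[None, :]) ** 2, axis=0)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
            np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    else:
        warnings.warn("empirical-Bayes iteration did not converge; using last iterate")
    return g_old, d_old


def _int_eprior(Z_b, g_hat, d_hat):
    """Nonparametric EB: posterior-weight each feature's (gamma, delta2) over the others'."""
    p = g_hat.size
    n_b = Z_b.shape[0]
    g_star = np.empty(p)
    d_star = np.empty(p)
    for j in range(p):
        x = Z_b[:, j]
        g, d = np.delete(g_hat, j), np.delete(d_hat, j)
        resid2 = (x[:, None] - g[None, :]) ** 2
        ll = -0.5 * resid2.sum(axis=0) / d - 0.5 * n_b * np.log(2 * np.pi * d)
        w = np.exp(ll - ll.max())
        w /= w.sum()
        g_star[j] = (w * g).sum()
        d_star[j] = (w * d).sum()
    return g_star, d_star


def combat(t: FeatureTable, design: BatchDesign, parametric: bool = True) -> FeatureTable:
    """Remove per-batch location and scale effects by empirical Bayes.

    Requires a complete (imputed/scaled) matrix.  With a single batch the
    input is returned unchanged (copy).  Shape and ids are preserved.
    """
    V = t.values.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValueError("combat requires a complete matrix; impute/scale first")
    if not design.batch.index.equals(t.values.index):
        raise ValueError("design and table sample ids differ")
    if design.n_batches == 1:
        return t.copy()

    n, p = V.shape
    batch_dummies = pd.get_dummies(design.batch, dtype=float)
    batches = list(batch_dummies.columns)
    B = batch_dummies.to_numpy()
    n_per_batch = B.sum(axis=0)
    X = B if design.covariates is None else np.column_stack([B, design.covariates.to_numpy(float)])

    # feature-wise OLS of Y on [batch indicators, covariates]
    beta, *_ = np.linalg.lstsq(X, V, rcond=None)
    n_batch = len(batches)
    grand_mean = (n_per_batch / n) @ beta[:n_batch, :]
    stand_mean = grand_mean[None, :] + (
        0.0 if design.covariates is None else design.covariates.to_numpy(float) @ beta[n_batch:, :]
    )
    var_pooled = ((V - X @ beta) ** 2).sum(axis=0) / n
    if (var_pooled <= 0).any():
        raise ValueError("zero pooled variance feature; drop constant features first")
    sd_pooled = np.sqrt(var_pooled)

    Z = (V - stand_mean) / sd_pooled[None, :]

    gamma_star = np.empty((n_batch, p))
    delta_star = np.empty((n_batch, p))
    for bi in range(n_batch):
        rows = B[:, bi] == 1
        Z_b = Z[rows]
        g_hat = Z_b.mean(axis=0)
        d_hat = Z_b.var(axis=0, ddof=1)
        if parametric:
            g_bar, t2 = g_hat.mean(), g_hat.var()
            a, b = _aprior(d_hat), _bprior(d_hat)
            gamma_star[bi], delta_star[bi] = _it_sol(Z_b, g_hat, d_hat, g_bar, t2, a, b)
        else:
            gamma_star[bi], delta_star[bi] = _int_eprior(Z_b, g_hat, d_hat)

    Z_adj = Z.copy()
    for bi in range(n_batch):
        rows = B[:, bi] == 1
        Z_adj[rows] = (Z[rows] - gamma_star[bi][None, :]) / np.sqrt(delta_star[bi])[None, :]

    out = t.copy()
    out.values = pd.DataFrame(
        Z_adj * sd_pooled[None, :] + stand_mean, index=t.values.index, columns=t.values.columns
    )
    return out


def surrogate_variables(
    t: FeatureTable,
    primary_design: pd.DataFrame,
    n_sv: int | None = None,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate hidden-factor score vectors from model residuals.

    Residualizes the matrix on ``primary_design`` (an intercept is added),
    takes the SVD of the residuals, and returns the top ``n_sv`` per-sample
    score vectors (left singular vectors scaled by singular values).  When
    ``n_sv`` is None it is chosen by comparing each singular value's
    variance share against its null distribution under ``n_perm``
    column-wise permutations of the residuals, keeping components whose
    share exceeds the ``1 - alpha`` null quantile.
    """
    V = t.values.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValueError("surrogate_variables requires a complete matrix")
    n, p = V.shape
    X = np.column_stack([np.ones(n), primary_design.to_numpy(float)])
    max_sv = min(n, p) - X.shape[1]
    if n_sv is not None and n_sv >= min(n, p):
        raise ValueError("n_sv must be smaller than min(n_samples, n_features)")

    H = X @ np.linalg.pinv(X)
    R = V - H @ V
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    share = s**2 / (s**2).sum()

    if n_sv is None:
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, s.size))
        for k in range(n_perm):
            Rp = np.empty_like(R)
            for j in range(p):
                Rp[:, j] = rng.permutation(R[:, j])
            Rp -= H @ Rp
            sp_ = np.linalg.svd(Rp, compute_uv=False)
            null[k] = sp_**2 / (sp_**2).sum()
        thresh = np.quantile(null, 1 - alpha, axis=0)
        above = share > thresh
        n_sv = 0
        while n_sv < max_sv and above[n_sv]:
            n_sv += 1
    scores = U[:, :n_sv] * s[:n_sv]
    return pd.DataFrame(
        scores, index=t.values.index, columns=[f"SV{k + 1}" for k in range(n_sv)]
    )
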