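"""Chromatogram-to-feature-table preprocessing chain.

The chain mirrors standard GC-MS peak-table practice: Savitzky–Golay noise
removal, asymmetric-least-squares baseline correction, SNR-gated
local-maximum peak picking with trapezoidal integration, tolerance-based
cross-sample alignment, total-intensity normalization, a per-class 20%
detection-prevalence filter, and log + Pareto (or unit-variance) scaling.
Each step is a plain function over the containers so alternatives can be
swapped in via the workflow configuration.

"Not detected" is represented as NaN throughout; only the final scaling
step imputes (half the feature's minimum detected value) so that the
prevalence filter operates on true detection patterns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import find_peaks, savgol_filter
from scipy.sparse.linalg import spsolve

from .containers import CLASSES, Chromatogram, FeatureTable, Peak, PeakList


def denoise(c: Chromatogram, window: int = 9, polyorder: int = 3) -> Chromatogram:
    """Savitzky–Golay smoothing along retention time, per m/z channel.

    ``window`` must be odd and larger than ``polyorder``; negative smoothed
    values are clipped at zero.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if window > c.rt.size:
        raise ValueError("window longer than the retention-time trace")
    smoothed = savgol_filter(c.intensity, window, polyorder, axis=0)
    return c.with_intensity(np.clip(smoothed, 0.0, None))


def _als_baseline(y: np.ndarray, lam: float, p: float, n_iter: int = 20, tol: float = 1e-6) -> np.ndarray:
    """Asymmetric penalized least squares (Whittaker smoother) baseline."""
    m = y.size
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m))
    DtD = lam * (D.T @ D)
    w = np.ones(m)
    z = y.copy()
    for _ in range(n_iter):
        W = sp.diags(w)
        z_new = spsolve((W + DtD).tocsc(), w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        if np.allclose(z_new, z, atol=tol * (np.abs(y).max() + 1e-12)):
            z = z_new
            break
        if np.array_equal(w_new, w):
            z = z_new
            break
        w, z = w_new, z_new
    else:
        warnings.warn("baseline estimation did not converge; using last iterate")
    return z


def correct_baseline(c: Chromatogram, lam: float = 1e7, p: float = 0.01) -> Chromatogram:
    """Estimate and subtract a slowly varying baseline per m/z channel.

    Uses asymmetric least squares: a second-difference-penalized fit in
    which points above the current baseline get weight ``p`` (peaks) and
    points below get ``1 - p``.  Result is clipped at zero.
    """
    if lam <= 0 or not 0.0 < p < 1.0:
        raise ValueError("require lambda > 0 and 0 < p < 1")
    out = np.empty_like(c.intensity)
    for ch in range(c.intensity.shape[1]):
        y = c.intensity[:, ch]
        if not y.any():
            out[:, ch] = 0.0
            continue
        out[:, ch] = y - _als_baseline(y, lam, p)
    return c.with_intensity(np.clip(out, 0.0, None))


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise scale from the upper half of the baseline fluctuations.

    Baseline-corrected traces are clipped at zero, which zeroes the lower
    half of the noise; the 84.1th percentile minus the median still
    estimates one noise standard deviation (peaks are sparse enough not to
    reach that quantile)."""
    return max(float(np.quantile(y, 0.841) - np.median(y)), 1e-12)


def pick_peaks(c: Chromatogram, snr_min: float = 5.0, min_width: float = 1.0) -> PeakList:
    """Detect local maxima with SNR >= ``snr_min`` and width >= ``min_width`` s.

    Peak area is the trapezoidal integral of the trace between the flanking
    local minima of each apex.  Expects a denoised, baseline-corrected
    chromatogram; returns an empty list for featureless traces.
    """
    dt = float(np.median(np.diff(c.rt)))
    width_pts = max(int(np.ceil(min_width / dt)), 1)
    peaks: list[Peak] = []
    for ch in range(c.intensity.shape[1]):
        y = c.intensity[:, ch]
        if not y.any():
            continue
        sigma = _noise_sigma(y)
        idx, props = find_peaks(
            y, height=snr_min * sigma, prominence=snr_min * sigma, width=width_pts
        )
        if idx.size == 0:
            continue
        # flanking minima: lowest point between consecutive apexes (and edges)
        bounds = np.concatenate(
            ([0], [int(y[a:b].argmin()) + a for a, b in zip(idx[:-1], idx[1:])], [y.size - 1])
        ).astype(int)
        for k, apex in enumerate(idx):
            left, right = bounds[k], bounds[k + 1]
            area = float(np.trapezoid(y[left : right + 1], c.rt[left : right + 1]))
            if area <= 0:
                continue
            peaks.append(
                Peak(
                    rt_apex=float(c.rt[apex]),
                    mz=float(c.mz_channels[ch]),
                    area=area,
                    height=float(y[apex]),
                    snr=float(y[apex] / sigma),
                )
            )
    peaks.sort(key=lambda pk: (pk.mz, pk.rt_apex))
    return PeakList(sample_id=c.sample_id, peaks=peaks)


def align_features(
    peaklists: list[PeakList], rt_tol: float = 2.0, rt_step: float | None = None
) -> FeatureTable:
    """Cluster peaks across samples into consensus features.

    Peaks match when their nominal m/z is identical and consecutive
    retention times differ by at most ``rt_tol`` seconds (single linkage
    within each m/z group).  One feature per cluster; a sample missing from
    a cluster gets NaN; a sample contributing several peaks to one cluster
    contributes their summed area.
    """
    if len(peaklists) < 2:
        raise ValueError("alignment needs at least 2 samples")
    rows = []
    for si, pl in enumerate(peaklists):
        for pk in pl.peaks:
            rows.append((si, pk.mz, pk.rt_apex, pk.area))
    sample_ids = [pl.sample_id or f"sample{ix}" for ix, pl in enumerate(peaklists)]
    if not rows:
        return FeatureTable(
            pd.DataFrame(index=pd.Index(sample_ids, name="sample")),
            pd.DataFrame(index=pd.Index(sample_ids, name="sample")),
        )
    df = pd.DataFrame(rows, columns=["si", "mz", "rt", "area"]).sort_values(["mz", "rt"])
    new_cluster = (df["mz"].diff() != 0) | (df["rt"].diff() > rt_tol)
    df["cluster"] = new_cluster.cumsum()

    consensus = df.groupby("cluster").agg(rt=("rt", "median"), mz=("mz", "first"))
    consensus = consensus.sort_values(["rt", "mz"])
    feat_ids = pd.Index([f"F{k:04d}" for k in range(len(consensus))], name="feature")
    cluster_to_feat = dict(zip(consensus.index, feat_ids))
    df["feature"] = df["cluster"].map(cluster_to_feat)

    values = (
        df.pivot_table(index="si", columns="feature", values="area", aggfunc="sum")
        .reindex(index=range(len(peaklists)), columns=feat_ids)
    )
    values.index = pd.Index(sample_ids, name="sample")
    feature_meta = consensus.set_index(feat_ids)
    sample_meta = pd.DataFrame(index=values.index)
    return FeatureTable(values, sample_meta, feature_meta)


def normalize(t: FeatureTable) -> FeatureTable:
    """Divide each sample's detected abundances by its total detected abundance."""
    totals = t.values.sum(axis=1, skipna=True)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"samples with no detected features: {list(empty.index)}")
    out = t.copy()
    out.values = t.values.div(totals, axis=0)
    return out


def prevalence_filter(t: FeatureTable, threshold: float = 0.20) -> FeatureTable:
    """Keep features detected in at least ``threshold`` of one disease class.

    The comparison is inclusive: a feature detected in exactly 20% of one
    class is kept.  Column order is preserved.
    """
    labels = t.classes
    if labels.isna().any() or not set(labels) <= set(CLASSES):
        raise ValueError("every sample needs a known class label")
    det = t.detected()
    frac = det.groupby(labels, observed=True).mean()
    keep = (frac >= threshold).any(axis=0)
    return t.subset_features(t.values.columns[keep])


def scale(t: FeatureTable, mode: str = "pareto") -> FeatureTable:
    """Log-transform, impute, center, and scale every feature column.

    Missing values are imputed as half the feature's minimum detected value
    (before the log), then each column is natural-log transformed, mean
    centered, and divided by its standard deviation ("unit") or the square
    root of its standard deviation ("pareto").  Constant columns are only
    centered, with a warning.
    """
    if mode not in ("unit", "pareto"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    vals = t.values.to_numpy(dtype=float).copy()
    mins = np.nanmin(np.where(np.isnan(vals), np.inf, vals), axis=0)
    if np.isinf(mins).any():
        bad = t.values.columns[np.isinf(mins)]
        raise ValueError(f"features never detected cannot be imputed: {list(bad)}")
    fill = np.where(np.isnan(vals), (mins / 2.0)[None, :], vals)
    logged = np.log(fill)
    centered = logged - logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    zero_var = sd <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s) centered but not scaled"
        )
    divisor = np.where(zero_var, 1.0, sd if mode == "unit" else np.sqrt(sd))
    out = t.copy()
    out.values = pd.DataFrame(centered / divisor, index=t.values.index, columns=t.values.columns)
    return out
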