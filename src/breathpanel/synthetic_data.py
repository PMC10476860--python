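"""Synthetic breath-VOC cohort generator with known ground truth.

No public breath data accompany FIT-positive screening cohorts, so every
downstream stage of the pipeline is exercised on synthetic cohorts whose
generating parameters are known exactly.  The generator emulates a
two-center TD-GC-MS screening study: four endoscopy-defined classes
(CRC / AA / NAA / negative control) with realistic prevalences, log-normal
peak-area abundances, a small set of marker compounds with signed per-class
shifts (positive sign = elevated in advanced-adenoma cases), multiplicative
per-batch location/scale instrument effects, and class-dependent detection
dropout.

Abundances are log-normal: class and batch effects act additively on the
natural-log scale, i.e. multiplicatively on the raw peak-area scale, which
is the behaviour empirical-Bayes batch correction is designed to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLASSES, Chromatogram, FeatureTable

#: Cohort composition of a FIT-positive screening population at colonoscopy.
DEFAULT_N_PER_CLASS = {"CRC": 30, "AA": 138, "NAA": 130, "control": 84}

#: Signed per-class log-abundance shifts applied to each marker, as a
#: multiple of the marker's sign.  Advanced lesions (AA, CRC) carry the full
#: effect; non-advanced adenomas a half effect; controls none.
DEFAULT_CLASS_EFFECT = {"AA": 1.0, "CRC": 1.0, "NAA": 0.5, "control": 0.0}

#: Per-class probability that a truly present compound is detected.
DEFAULT_DROPOUT = {"CRC": 0.9, "AA": 0.9, "NAA": 0.85, "control": 0.85}


@dataclass
class CohortSpec:
    """Generating parameters for one synthetic cohort.

    Parameters
    ----------
    n_per_class : dict
        Samples per class; defaults to the screening-cohort composition
        (30 CRC, 138 AA, 130 NAA, 84 controls; 382 total).
    n_features : int
        Number of VOC features on the peak table.
    n_markers : int
        Number of planted marker compounds (default 10).
    effect_sizes : dict, class -> float
        Magnitude of the log-scale shift per class, multiplied by each
        marker's sign (+1 = higher in AA).
    marker_signs : sequence of ±1, optional
        Sign per marker; default alternates starting at +1.
    dropout : dict, class -> float
        Detection probability per class (independent Bernoulli per
        feature and sample).
    censor_quantile : float or None
        If set, additionally censor (mark undetected) any measurement whose
        latent abundance falls below this quantile of its feature's latent
        distribution — missing-not-at-random dropout.
    n_batches : int
        Instrument batches (2 = two study centers).
    batch_location_sd, batch_scale_sd : float
        Dispersion of per-batch, per-feature additive log-location effects
        and of the log of the multiplicative residual-scale effects.
    noise_sd : float
        Within-class log-scale biological + technical noise.
    baseline_log_mean, baseline_log_sd : float
        Per-feature baseline log-abundance is drawn N(mean, sd).
    rng_seed : int
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    n_features: int = 200
    n_markers: int = 10
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_EFFECT))
    marker_signs: tuple[int, ...] | None = None
    dropout: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DROPOUT))
    censor_quantile: float | None = None
    n_batches: int = 2
    batch_location_sd: float = 0.3
    batch_scale_sd: float = 0.2
    noise_sd: float = 1.0
    baseline_log_mean: float = 9.0
    baseline_log_sd: float = 1.0
    rng_seed: int = 0
    # chromatogram rendering parameters
    rt_range: tuple[float, float] = (60.0, 1140.0)
    rt_step: float = 0.5
    n_mz_channels: int = 40
    peak_sigma: float = 2.0
    rt_jitter_sd: float = 0.4
    chrom_baseline_amp: float = 0.0
    chrom_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_class) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in n_per_class: {sorted(unknown)}")
        if any(n <= 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be positive")
        if self.n_features <= 0 or self.n_markers < 0:
            raise ValueError("n_features must be > 0 and n_markers >= 0")
        if self.n_markers > self.n_features:
            raise ValueError("n_markers cannot exceed n_features")
        if set(self.dropout) != set(self.n_per_class):
            raise ValueError("dropout must give one detection probability per class")
        if any(not 0.0 <= p <= 1.0 for p in self.dropout.values()):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if set(self.effect_sizes) != set(self.n_per_class):
            raise ValueError("effect_sizes must give one shift per class")
        if self.n_batches <= 0:
            raise ValueError("n_batches must be positive")
        if self.marker_signs is None:
            self.marker_signs = tuple((-1) ** k for k in range(self.n_markers))
        self.marker_signs = tuple(int(s) for s in self.marker_signs)
        if len(self.marker_signs) != self.n_markers:
            raise ValueError("marker_signs length must equal n_markers")
        if any(s not in (-1, 1) for s in self.marker_signs):
            raise ValueError("marker signs must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_class.values())

    @property
    def feature_ids(self) -> list[str]:
        return [f"VOC{j:04d}" for j in range(self.n_features)]


@dataclass
class GroundTruth:
    """What the generator planted, for recovery experiments.

    ``true_log_abundance`` holds the latent (pre-dropout, pre-batch)
    log-abundances so that end-to-end preprocessing recovery can be scored
    by rank correlation.
    """

    marker_indices: list[str]
    marker_signs: dict[str, int]
    class_labels: pd.Series
    batch_assignments: pd.Series
    effect_sizes: dict[str, float]
    true_log_abundance: pd.DataFrame | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        same_latent = (
            (self.true_log_abundance is None) == (other.true_log_abundance is None)
        ) and (
            self.true_log_abundance is None
            or np.allclose(self.true_log_abundance.values, other.true_log_abundance.values)
        )
        return (
            self.marker_indices == other.marker_indices
            and self.marker_signs == other.marker_signs
            and self.class_labels.equals(other.class_labels)
            and self.batch_assignments.equals(other.batch_assignments)
            and self.effect_sizes == other.effect_sizes
            and same_latent
        )


def _feature_map(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic RT / m/z assignment for every feature of a spec."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0xFEA7]))
    lo, hi = spec.rt_range
    rt = np.sort(rng.uniform(lo + 10.0, hi - 10.0, size=spec.n_features))
    # enforce a minimal spacing so peaks sharing an m/z channel stay resolvable
    min_gap = 6.0 * spec.peak_sigma
    channels = rng.integers(0, spec.n_mz_channels, size=spec.n_features)
    for ch in range(spec.n_mz_channels):
        idx = np.flatnonzero(channels == ch)
        for a, b in zip(idx[:-1], idx[1:]):
            if rt[b] - rt[a] < min_gap:
                rt[b] = rt[a] + min_gap
    mz = 30 + channels * 5
    return pd.DataFrame({"rt": rt, "mz": mz}, index=pd.Index(spec.feature_ids, name="feature"))


def generate_feature_table(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort: a sample x feature peak table plus its ground truth.

    The latent model for sample *i* (class c, batch b) and feature *j* is::

        log A_ij = mu_j + beta_j(c) + gamma_bj + delta_bj * eps_ij

    with ``mu_j ~ N(baseline_log_mean, baseline_log_sd)``, marker effect
    ``beta_j(c) = sign_j * effect_sizes[c]`` (0 for non-markers),
    ``gamma_bj ~ N(0, batch_location_sd)``,
    ``delta_bj = exp(N(0, batch_scale_sd))`` and
    ``eps_ij ~ N(0, noise_sd)``.  Detection dropout then replaces a subset
    of measurements with NaN.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0xC0C0]))
    classes = np.concatenate(
        [np.repeat(c, n) for c, n in spec.n_per_class.items()]
    )
    n, p = classes.size, spec.n_features
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    feature_ids = pd.Index(spec.feature_ids, name="feature")

    batches = rng.integers(0, spec.n_batches, size=n)
    mu = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=p)

    marker_idx = rng.choice(p, size=spec.n_markers, replace=False)
    signs = np.asarray(spec.marker_signs, dtype=float)
    beta = np.zeros((len(CLASSES), p))
    for ci, c in enumerate(CLASSES):
        if c in spec.effect_sizes:
            beta[ci, marker_idx] = signs * spec.effect_sizes[c]
    class_codes = np.array([CLASSES.index(c) for c in classes])

    gamma = rng.normal(0.0, spec.batch_location_sd, size=(spec.n_batches, p))
    delta = np.exp(rng.normal(0.0, spec.batch_scale_sd, size=(spec.n_batches, p)))
    eps = rng.normal(0.0, spec.noise_sd, size=(n, p))

    latent = mu[None, :] + beta[class_codes, :]
    log_abund = latent + gamma[batches, :] + delta[batches, :] * eps
    raw = np.exp(log_abund)

    detect_p = np.array([spec.dropout[c] for c in classes])[:, None]
    detected = rng.random((n, p)) < detect_p
    if spec.censor_quantile is not None:
        # MNAR: censor draws whose latent value sits in the feature's lower tail
        thresh = np.quantile(log_abund, spec.censor_quantile, axis=0)
        detected &= log_abund > thresh[None, :]

    values = pd.DataFrame(np.where(detected, raw, np.nan), index=sample_ids, columns=feature_ids)
    sample_meta = pd.DataFrame(
        {"class": classes, "batch": [f"B{b}" for b in batches]}, index=sample_ids
    )
    feature_meta = _feature_map(spec)

    marker_ids = [feature_ids[j] for j in sorted(marker_idx)]
    order = np.argsort(marker_idx)
    sign_by_id = {feature_ids[marker_idx[k]]: int(signs[k]) for k in range(spec.n_markers)}
    del order
    truth = GroundTruth(
        marker_indices=marker_ids,
        marker_signs=sign_by_id,
        class_labels=sample_meta["class"].copy(),
        batch_assignments=sample_meta["batch"].copy(),
        effect_sizes=dict(spec.effect_sizes),
        true_log_abundance=pd.DataFrame(latent + eps, index=sample_ids, columns=feature_ids),
    )
    return FeatureTable(values, sample_meta, feature_meta), truth


def generate_chromatogram(
    sample_row: np.ndarray | pd.Series, spec: CohortSpec, seed: int
) -> Chromatogram:
    """Render one sample's abundance vector as a synthetic TD-GC-MS trace.

    Each feature becomes a Gaussian retention-time peak (sd ``peak_sigma``
    seconds) in its assigned m/z channel, with *area* equal to the feature's
    abundance; undetected features (NaN) are omitted.  A per-sample RT
    jitter, an optional slowly-varying baseline and additive Gaussian noise
    emulate instrument imperfection.
    """
    if isinstance(sample_row, pd.Series):
        sample_id = str(sample_row.name) if sample_row.name is not None else ""
        abund = sample_row.to_numpy(dtype=float)
    else:
        sample_id = ""
        abund = np.asarray(sample_row, dtype=float)
    if abund.size != spec.n_features:
        raise ValueError("abundance vector length does not match spec.n_features")
    if np.nanmin(abund, initial=0.0) < 0:
        raise ValueError("abundances must be nonnegative")

    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0xCB04, int(seed)]))
    fmap = _feature_map(spec)
    lo, hi = spec.rt_range
    rt = np.arange(lo, hi + spec.rt_step / 2, spec.rt_step)
    channels = np.arange(spec.n_mz_channels)
    mz_channels = 30 + channels * 5
    intensity = np.zeros((rt.size, spec.n_mz_channels))

    jitter = rng.normal(0.0, spec.rt_jitter_sd)
    sig = spec.peak_sigma
    for j in range(spec.n_features):
        a = abund[j]
        if not np.isfinite(a) or a == 0.0:
            continue
        center = fmap["rt"].iloc[j] + jitter
        ch = int((fmap["mz"].iloc[j] - 30) // 5)
        prof = np.exp(-0.5 * ((rt - center) / sig) ** 2)
        intensity[:, ch] += a * prof / (sig * np.sqrt(2 * np.pi))

    if spec.chrom_baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        drift = 0.5 * (1 + np.sin(2 * np.pi * (rt - lo) / (hi - lo) + phase))
        intensity += spec.chrom_baseline_amp * drift[:, None]
    if spec.chrom_noise_sd > 0:
        intensity += rng.normal(0.0, spec.chrom_noise_sd, size=intensity.shape)
        np.clip(intensity, 0.0, None, out=intensity)

    return Chromatogram(rt=rt, mz_channels=mz_channels, intensity=intensity, sample_id=sample_id)


def write_dataset(table: FeatureTable, truth: GroundTruth, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to ``directory`` as CSV + JSON; lossless round-trip.

    Missing values are written as empty cells (not zeros).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": directory / "feature_table.csv",
        "sample_meta": directory / "sample_metadata.csv",
        "feature_meta": directory / "feature_metadata.csv",
        "truth": directory / "ground_truth.json",
    }
    table.values.to_csv(paths["values"])
    table.sample_meta.to_csv(paths["sample_meta"])
    if table.feature_meta is not None:
        table.feature_meta.to_csv(paths["feature_meta"])
    payload = {
        "marker_indices": truth.marker_indices,
        "marker_signs": truth.marker_signs,
        "class_labels": truth.class_labels.to_dict(),
        "batch_assignments": truth.batch_assignments.to_dict(),
        "effect_sizes": truth.effect_sizes,
        "true_log_abundance": None
        if truth.true_log_abundance is None
        else {
            "index": list(truth.true_log_abundance.index),
            "columns": list(truth.true_log_abundance.columns),
            "data": truth.true_log_abundance.to_numpy().tolist(),
        },
    }
    paths["truth"].write_text(json.dumps(payload))
    return paths


def read_dataset(directory: str | Path) -> tuple[FeatureTable, GroundTruth | None]:
    """Inverse of :func:`write_dataset`; tolerates a missing ground-truth file."""
    directory = Path(directory)
    values = pd.read_csv(directory / "feature_table.csv", index_col=0)
    values.index.name = "sample"
    values.columns.name = "feature"
    sample_meta = pd.read_csv(directory / "sample_metadata.csv", index_col=0)
    sample_meta.index.name = "sample"
    fmeta_path = directory / "feature_metadata.csv"
    feature_meta = None
    if fmeta_path.exists():
        feature_meta = pd.read_csv(fmeta_path, index_col=0)
        feature_meta.index.name = "feature"
    table = FeatureTable(values, sample_meta, feature_meta)

    truth = None
    tpath = directory / "ground_truth.json"
    if tpath.exists():
        payload = json.loads(tpath.read_text())
        tla = payload["true_log_abundance"]
        truth = GroundTruth(
            marker_indices=payload["marker_indices"],
            marker_signs={k: int(v) for k, v in payload["marker_signs"].items()},
            class_labels=pd.Series(payload["class_labels"]).reindex(values.index),
            batch_assignments=pd.Series(payload["batch_assignments"]).reindex(values.index),
            effect_sizes={k: float(v) for k, v in payload["effect_sizes"].items()},
            true_log_abundance=None
            if tla is None
            else pd.DataFrame(tla["data"], index=tla["index"], columns=tla["columns"]),
        )
        truth.class_labels.index.name = "sample"
        truth.batch_assignments.index.name = "sample"
    return table, truth
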