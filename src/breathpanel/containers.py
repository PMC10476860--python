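"""Core data containers shared across the pipeline.

A breath sample starts life as a :class:`Chromatogram` (retention-time x m/z
intensity grid from TD-GC-MS), is reduced to a :class:`PeakList`, and the
cohort's peak lists are aligned into a :class:`FeatureTable` — the sample x
VOC-feature abundance matrix that every downstream model consumes.  A missing
value in the table means *not detected*, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASSES = ("CRC", "AA", "NAA", "control")


@dataclass
class Chromatogram:
    """Retention-time x m/z intensity grid for one breath sample.

    Parameters
    ----------
    rt : ndarray, shape (n_rt,)
        Retention-time grid in seconds, strictly increasing.
    mz_channels : ndarray, shape (n_mz,)
        Nominal m/z bin of each intensity column.
    intensity : ndarray, shape (n_rt, n_mz)
        Non-negative ion intensities.
    sample_id : str
    """

    rt: np.ndarray
    mz_channels: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz_channels = np.asarray(self.mz_channels)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt grid must be 1-D and strictly increasing")
        if self.intensity.shape != (self.rt.size, self.mz_channels.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"(n_rt={self.rt.size}, n_mz={self.mz_channels.size})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def with_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class Peak:
    rt_apex: float
    mz: float
    area: float
    height: float
    snr: float


@dataclass
class PeakList:
    """Picked peaks for one sample: (rt apex, m/z bin, area, height, SNR)."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.rt_apex, p.mz, p.area, p.height, p.snr) for p in self.peaks],
            columns=["rt_apex", "mz", "area", "height", "snr"],
        )


@dataclass
class FeatureTable:
    """Sample x feature abundance matrix with sample and feature metadata.

    ``values`` is a pandas DataFrame (rows = samples, columns = features);
    NaN encodes *not detected*.  ``sample_meta`` carries at least ``class``
    and ``batch`` columns; ``feature_meta`` carries consensus ``rt`` and
    ``mz`` where known.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("sample and feature ids must be unique")
        if not self.values.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.reindex(self.values.index)
            if self.sample_meta.isna().all(axis=1).any():
                raise ValueError("sample_meta does not cover all samples")
        if "class" in self.sample_meta:
            bad = set(self.sample_meta["class"].dropna()) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown class labels: {sorted(bad)}")
        if self.feature_meta is not None and not self.feature_meta.index.equals(
            self.values.columns
        ):
            self.feature_meta = self.feature_meta.reindex(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> pd.Series:
        return self.sample_meta["class"]

    @property
    def batches(self) -> pd.Series:
        return self.sample_meta["batch"]

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (True where the feature was measured)."""
        return self.values.notna()

    def subset_features(self, feature_ids) -> "FeatureTable":
        fm = None if self.feature_meta is None else self.feature_meta.loc[feature_ids]
        return FeatureTable(self.values[list(feature_ids)].copy(), self.sample_meta.copy(), fm)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[list(sample_ids)].copy(),
            self.sample_meta.loc[list(sample_ids)].copy(),
            None if self.feature_meta is None else self.feature_meta.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            self.sample_meta.copy(),
            None if self.feature_meta is None else self.feature_meta.copy(),
        )
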