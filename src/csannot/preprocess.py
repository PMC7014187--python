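"""Spectrum preprocessing: recalibration, rank-window normalization, alignment, filtering.

The stages mirror a direct-infusion plasma metabolomics workflow:

1. single-point multiplicative m/z recalibration to an internal standard
   (losartan, m/z 423.169);
2. per-peak intensity normalization by the 150th-most-intense peak inside a
   50 Da window centred on the peak (an ion-suppression correction that makes
   intensities comparable across the m/z axis and across samples);
3. gap-based alignment of peaks across samples into features;
4. removal of features detected in too few samples (more than ``min_samples``
   nonzero values required, default strictly more than nine).

Each stage is available both as a function and as a scikit-learn style
transformer operating on lists of :class:`PeakSpectrum`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSpectrum",
    "AlignedPeakTable",
    "recalibrate",
    "normalize",
    "align",
    "filter_features",
    "SpectrumRecalibrator",
    "RankWindowNormalizer",
    "PeakAligner",
    "FeatureFilter",
]

REFERENCE_MZ = 423.169  # losartan internal standard, [M+H]+


@dataclass
class PeakSpectrum:
    """One sample's centroided peak list (m/z in Da, intensity in arbitrary units)."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError(f"{self.sample_id}: m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError(f"{self.sample_id}: intensities must be non-negative")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class AlignedPeakTable:
    """Features x samples intensity matrix; zero means not detected."""

    feature_ids: list[str]
    mz: np.ndarray                      # consensus m/z per feature, increasing
    intensities: np.ndarray             # shape (n_features, n_samples)
    sample_ids: list[str]
    sample_meta: pd.DataFrame | None = field(default=None)  # indexed by sample_id

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def nonzero_counts(self) -> np.ndarray:
        return (self.intensities > 0).sum(axis=1)

    def with_metadata(self, manifest: pd.DataFrame) -> "AlignedPeakTable":
        meta = manifest.set_index("sample_id").loc[self.sample_ids]
        return AlignedPeakTable(self.feature_ids, self.mz, self.intensities,
                                self.sample_ids, meta)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.intensities, columns=self.sample_ids)
        df.insert(0, "mz", self.mz)
        df.insert(0, "feature_id", self.feature_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, manifest: pd.DataFrame | None = None
                 ) -> "AlignedPeakTable":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("feature_id", "mz")]
        table = cls(df["feature_id"].astype(str).tolist(), df["mz"].to_numpy(float),
                    df[samples].to_numpy(float), samples)
        return table.with_metadata(manifest) if manifest is not None else table


def recalibrate(spectrum: PeakSpectrum, reference_mz: float = REFERENCE_MZ,
                window: float = 0.05) -> PeakSpectrum:
    """Single-point multiplicative m/z correction to the internal standard.

    The peak closest to ``reference_mz`` within ``±window`` defines the scale
    factor ``reference_mz / observed_mz`` applied to every m/z. Ties in
    closeness are broken toward the more intense peak. Without a standard
    peak the spectrum is returned unchanged and a warning logged.
    """
    lo = np.searchsorted(spectrum.mz, reference_mz - window, side="left")
    hi = np.searchsorted(spectrum.mz, reference_mz + window, side="right")
    if hi <= lo:
        logger.warning("%s: no peak within %.3g Da of internal standard %.4f; "
                       "spectrum left unrecalibrated", spectrum.sample_id, window,
                       reference_mz)
        return spectrum
    cand_mz = spectrum.mz[lo:hi]
    cand_int = spectrum.intensity[lo:hi]
    err = np.abs(cand_mz - reference_mz)
    best = err.min()
    tied = np.flatnonzero(np.isclose(err, best, rtol=0.0, atol=1e-9))
    if tied.size > 1:
        logger.info("%s: %d equally close standard candidates; using the most intense",
                    spectrum.sample_id, tied.size)
        pick = tied[np.argmax(cand_int[tied])]
    else:
        pick = tied[0]
    factor = reference_mz / cand_mz[pick]
    return PeakSpectrum(spectrum.sample_id, spectrum.mz * factor, spectrum.intensity)


def normalize(spectrum: PeakSpectrum, window: float = 50.0, rank: int = 150
              ) -> PeakSpectrum:
    """Divide each intensity by the ``rank``-th most intense peak nearby.

    For a peak at m/z ``m`` the normalization value is found among all peaks
    (the peak itself included) with m/z in ``[m - window/2, m + window/2]``,
    sorted by intensity in descending order; entry number ``rank`` is the
    divisor. Windows holding fewer than ``rank`` peaks use their least
    intense peak, so a single-peak window normalizes to one. All divisors
    are computed from the raw input before any division, making the result
    invariant to a global intensity rescaling of the spectrum.
    """
    if spectrum.n_peaks == 0:
        return spectrum
    if rank < 1:
        raise ValueError("rank must be >= 1")
    half = window / 2.0
    mz, raw = spectrum.mz, spectrum.intensity
    lo = np.searchsorted(mz, mz - half, side="left")
    hi = np.searchsorted(mz, mz + half, side="right")
    out = np.empty_like(raw)
    for i in range(mz.size):
        win = raw[lo[i]:hi[i]]
        if win.size >= rank:
            v = np.partition(win, win.size - rank)[win.size - rank]
        else:
            v = win.min()
        if v <= 0:
            logger.warning("%s: zero normalization value at m/z %.4f; peak left as-is",
                           spectrum.sample_id, mz[i])
            out[i] = raw[i]
        else:
            out[i] = raw[i] / v
    return PeakSpectrum(spectrum.sample_id, mz.copy(), out)


def align(spectra: list[PeakSpectrum], tolerance: float = 0.005) -> AlignedPeakTable:
    """Cluster pooled peaks into cross-sample features by m/z gap cutting.

    All peaks from all spectra are pooled and sorted by m/z; the sorted list
    is cut wherever the gap between adjacent peaks exceeds ``tolerance``
    (single linkage). Consensus m/z is the intensity-weighted mean of the
    members; two peaks of one sample falling in one feature have their
    intensities summed.
    """
    if len(spectra) < 2:
        raise ValueError("alignment needs at least two spectra")
    sample_ids = [s.sample_id for s in spectra]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id among spectra")
    mz_all = np.concatenate([s.mz for s in spectra])
    int_all = np.concatenate([s.intensity for s in spectra])
    samp_all = np.concatenate([np.full(s.n_peaks, k) for k, s in enumerate(spectra)])
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all, samp_all = mz_all[order], int_all[order], samp_all[order]

    if mz_all.size == 0:
        return AlignedPeakTable([], np.empty(0), np.zeros((0, len(spectra))), sample_ids)
    cut = np.flatnonzero(np.diff(mz_all) > tolerance) + 1
    feat = np.zeros(mz_all.size, dtype=int)
    feat[cut] = 1
    feat = np.cumsum(feat)
    n_feat = feat[-1] + 1

    matrix = np.zeros((n_feat, len(spectra)))
    np.add.at(matrix, (feat, samp_all), int_all)
    wsum = np.bincount(feat, weights=int_all, minlength=n_feat)
    wmz = np.bincount(feat, weights=int_all * mz_all, minlength=n_feat)
    cnt = np.bincount(feat, minlength=n_feat)
    plain = np.bincount(feat, weights=mz_all, minlength=n_feat) / cnt
    consensus = np.where(wsum > 0, wmz / np.where(wsum > 0, wsum, 1.0), plain)

    width = len(str(n_feat))
    ids = [f"F{i + 1:0{width}d}" for i in range(n_feat)]
    return AlignedPeakTable(ids, consensus, matrix, sample_ids)


def filter_features(table: AlignedPeakTable, min_samples: int = 9) -> AlignedPeakTable:
    """Keep features with a nonzero intensity in strictly more than ``min_samples`` samples."""
    keep = table.nonzero_counts() > min_samples
    if not keep.any():
        logger.warning("feature filter removed every feature (min_samples=%d)", min_samples)
    return AlignedPeakTable(
        [f for f, k in zip(table.feature_ids, keep) if k],
        table.mz[keep], table.intensities[keep], list(table.sample_ids),
        table.sample_meta)


# ---------------------------------------------------------------------------
# scikit-learn style transformer surface
# ---------------------------------------------------------------------------

class _SpectrumListTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer over lists of PeakSpectrum (fit is a no-op)."""

    def fit(self, X, y=None):
        self._validate(X)
        self.n_spectra_ = len(X)
        return self

    @staticmethod
    def _validate(X):
        if not all(isinstance(s, PeakSpectrum) for s in X):
            raise TypeError("X must be a list of PeakSpectrum")


class SpectrumRecalibrator(_SpectrumListTransformer):
    def __init__(self, reference_mz: float = REFERENCE_MZ, window: float = 0.05):
        self.reference_mz = reference_mz
        self.window = window

    def transform(self, X):
        self._validate(X)
        return [recalibrate(s, self.reference_mz, self.window) for s in X]


class RankWindowNormalizer(_SpectrumListTransformer):
    def __init__(self, window: float = 50.0, rank: int = 150):
        self.window = window
        self.rank = rank

    def transform(self, X):
        self._validate(X)
        return [normalize(s, self.window, self.rank) for s in X]


class PeakAligner(_SpectrumListTransformer):
    """Aligns a list of spectra into an AlignedPeakTable."""

    def __init__(self, tolerance: float = 0.005):
        self.tolerance = tolerance

    def transform(self, X):
        self._validate(X)
        return align(X, self.tolerance)


class FeatureFilter(BaseEstimator, TransformerMixin):
    def __init__(self, min_samples: int = 9):
        self.min_samples = min_samples

    def fit(self, X, y=None):
        return self

    def transform(self, X: AlignedPeakTable) -> AlignedPeakTable:
        return filter_features(X, self.min_samples)
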