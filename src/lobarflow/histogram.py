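"""HU-histogram statistics over masked lung regions.

The density signature of a lung region is summarised by the normalized
histogram of its voxel HU values together with four moments:

* mean and median HU — overall density (air ≈ −1000, water ≈ 0);
* skewness — asymmetry of the distribution,
  ``skew = m3 / σ³`` with ``m3`` the third central moment;
* kurtosis — weight of the tails, ``kurt = m4 / σ⁴`` (non-excess: a
  normal distribution scores 3).

All moments use the population (n-denominator) convention and are computed
from the raw voxel values, not from binned counts — the histogram bin width
affects plotting only. Fibrotic lung raises the mean (tissue replaces air)
and flattens the sharp air peak, lowering both skewness and kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CtVolume, LOBE_NAMES, LobeLabelMap

__all__ = [
    "HistogramSummary",
    "normalized_histogram",
    "moment_mean",
    "moment_median",
    "skewness",
    "kurtosis",
    "summarize_region",
    "summarize_lobes",
]


@dataclass
class HistogramSummary:
    """Normalized HU histogram plus moment statistics for one region."""

    bin_edges: np.ndarray
    bin_probabilities: np.ndarray
    mean: float
    median: float
    sigma: float
    skewness: float
    kurtosis: float
    n_voxels: int


def _values(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty input")
    return arr


def normalized_histogram(values, bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram normalized by the total number of occurrences.

    Bins of width ``bin_width`` cover ``[min(values), max(values)]``;
    the returned probabilities sum to 1.
    """
    arr = _values(values)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = float(arr.min()), float(arr.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(arr, bins=edges)
    return edges, counts / arr.size


def moment_mean(values) -> float:
    """Arithmetic mean."""
    return float(np.mean(_values(values)))


def moment_median(values) -> float:
    """Median; for even counts, the mean of the two central order statistics."""
    return float(np.median(_values(values)))


def _central_moments(values) -> tuple[float, float, float, float]:
    arr = _values(values)
    if arr.size < 2:
        raise ValueError("need at least 2 values for shape statistics")
    dev = arr - arr.mean()
    var = float(np.mean(dev**2))
    if var == 0:
        raise ValueError("zero variance: skewness/kurtosis undefined")
    return var, float(np.mean(dev**3)), float(np.mean(dev**4)), arr.size


def skewness(values) -> float:
    """Population skewness m3/σ³ (no small-sample correction)."""
    var, m3, _, _ = _central_moments(values)
    return m3 / var**1.5


def kurtosis(values) -> float:
    """Population non-excess kurtosis m4/σ⁴ (normal distribution → 3)."""
    var, _, m4, _ = _central_moments(values)
    return m4 / var**2


def summarize_region(volume: CtVolume, mask: np.ndarray, bin_width: float = 1.0) -> HistogramSummary:
    """Full :class:`HistogramSummary` for the voxels selected by ``mask``.

    Vasculature voxels are deliberately not excluded: the soft-tissue peak
    near 0 HU they produce is part of the region's density signature.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {volume.shape}")
    vals = volume.voxels[mask].astype(float)
    if vals.size < 2:
        raise ValueError("mask selects fewer than 2 voxels")
    edges, probs = normalized_histogram(vals, bin_width)
    dev = vals - vals.mean()
    var = float(np.mean(dev**2))
    if var == 0:
        raise ValueError("zero variance in region")
    return HistogramSummary(
        bin_edges=edges,
        bin_probabilities=probs,
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        sigma=float(np.sqrt(var)),
        skewness=float(np.mean(dev**3)) / var**1.5,
        kurtosis=float(np.mean(dev**4)) / var**2,
        n_voxels=int(vals.size),
    )


def summarize_lobes(
    volume: CtVolume, labels: LobeLabelMap, bin_width: float = 1.0
) -> dict[str, HistogramSummary]:
    """Per-lobe histogram summaries, keyed by lobe name (RU, RL, LL, LU)."""
    return {
        name: summarize_region(volume, labels.mask(name), bin_width)
        for name in LOBE_NAMES
        if np.count_nonzero(labels.mask(name)) >= 2
    }
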