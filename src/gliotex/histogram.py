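"""Global intensity features: the four histogram moments of the ROI.

Moments are population moments (divide by N, not N-1) of the raw in-ROI
gray values, computed before any gray-level quantization:

    mean     = (1/N) sum P_i
    variance = (1/N) sum (P_i - mean)^2
    skewness = (1/N) sum ((P_i - mean)/std)^3
    kurtosis = (1/N) sum ((P_i - mean)/std)^4     (non-excess: normal -> 3)

A constant ROI has variance 0; skewness and kurtosis are then set to 0 by
convention and the result flagged degenerate, so no NaN reaches the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HISTOGRAM_FEATURE_NAMES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
)


@dataclass(frozen=True)
class HistogramMoments:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    degenerate: bool = False

    @property
    def std(self) -> float:
        return float(np.sqrt(self.variance))

    def as_dict(self) -> dict:
        return {
            "hist_mean": self.mean,
            "hist_variance": self.variance,
            "hist_skewness": self.skewness,
            "hist_kurtosis": self.kurtosis,
        }


def histogram_moments(pixels) -> HistogramMoments:
    """Compute mean, variance, skewness and (non-excess) kurtosis.

    Parameters
    ----------
    pixels : array-like of float
        The in-ROI gray values, N >= 1.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty pixel list")
    mean = float(x.mean())
    dev = x - mean
    variance = float(np.mean(dev**2))
    if variance == 0.0:
        return HistogramMoments(mean, 0.0, 0.0, 0.0, degenerate=True)
    std = np.sqrt(variance)
    z = dev / std
    return HistogramMoments(
        mean=mean,
        variance=variance,
        skewness=float(np.mean(z**3)),
        kurtosis=float(np.mean(z**4)),
    )
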