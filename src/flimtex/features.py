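"""First-order lifetime-histogram statistics of a cell's ROI.

Eight numbers summarise each cell: mean, standard deviation, skewness,
Shannon entropy, and the 5th/95th percentiles of the per-pixel lifetime
distribution inside the ROI, plus the same four moment/entropy statistics
recomputed after the LBP transform (see :mod:`flimtex.lbp`).

Entropy is computed on a normalised histogram over equal-width bins
spanning the ROI's own ``[min, max]`` range.  The bin count (default 32)
and logarithm base are free parameters: the absolute entropy scale of any
published table depends on an unstated binning, so entropies are only
comparable within one configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import as_lifetime_matrix

__all__ = ["HistogramFeatures", "histogram_stats", "percentile", "shannon_entropy"]

_LOG_BASE = {"e": None, "2": 2.0, "10": 10.0}


def _base_value(entropy_base) -> float | None:
    key = str(entropy_base)
    if key not in _LOG_BASE:
        raise ValueError(f"entropy_base must be one of {sorted(_LOG_BASE)}, got {entropy_base!r}")
    return _LOG_BASE[key]


@dataclass(frozen=True)
class HistogramFeatures:
    """First-order statistics of the ROI lifetime histogram (ps units)."""

    mean_ps: float
    sd_ps: float
    skewness: float
    entropy: float
    p5_ps: float
    p95_ps: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_ps": self.mean_ps,
            "sd_ps": self.sd_ps,
            "skewness": self.skewness,
            "entropy": self.entropy,
            "p5_ps": self.p5_ps,
            "p95_ps": self.p95_ps,
        }


def percentile(values, q: float) -> float:
    """Empirical quantile at fraction ``q`` with linear interpolation.

    ``q=0`` returns the minimum, ``q=1`` the maximum.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("percentile of empty input")
    if np.isnan(v).any():
        raise ValueError("percentile input contains NaN")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return float(np.quantile(v, q, method="linear"))


def shannon_entropy(values, bins: int = 32, base="e") -> float:
    """Shannon entropy of the equal-width histogram of *values*.

    Bins span the sample's own [min, max]; a constant sample has zero
    entropy by convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("entropy of empty input")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=bins, range=(lo, hi))
    return float(sps.entropy(counts, base=_base_value(base)))


def histogram_stats(roi, entropy_bins: int = 32, entropy_base="e") -> HistogramFeatures:
    """Compute the six per-ROI histogram statistics.

    Moment statistics use the population (biased) conventions: SD with
    divisor n, skewness as the Fisher-Pearson coefficient m3 / m2^1.5.
    A constant ROI yields SD 0, entropy 0 and, by convention, skewness 0
    (a warning flags the degenerate case).
    """
    roi = as_lifetime_matrix(roi)
    v = roi.ravel()
    if v.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    if np.isnan(v).any():
        raise ValueError("ROI contains NaN pixels; statistics undefined")

    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    if sd == 0.0:
        warnings.warn("constant ROI: skewness and entropy reported as 0", stacklevel=2)
        skew = 0.0
    else:
        skew = float(sps.skew(v, bias=True))
    return HistogramFeatures(
        mean_ps=mean,
        sd_ps=sd,
        skewness=skew,
        entropy=shannon_entropy(v, bins=entropy_bins, base=entropy_base),
        p5_ps=percentile(v, 0.05),
        p95_ps=percentile(v, 0.95),
    )
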