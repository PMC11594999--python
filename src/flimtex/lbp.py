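"""Rotation-invariant uniform Local Binary Patterns (riu2).

The LBP code of a pixel compares the centre intensity ``g_c`` with P
neighbours ``g_i`` sampled on a circle of radius R (bilinear interpolation
at non-integer positions):

    LBP_{P,R}(x, y) = sum_i s(g_i - g_c) * 2^i,     s(x) = 1 iff x >= 0.

The riu2 variant collapses every *uniform* pattern (at most two circular
0<->1 transitions, counted by the uniformity function U) to its number of
set bits, and every non-uniform pattern to the sentinel P + 1:

    riu2(bits) = popcount(bits)  if U(bits) <= 2,  else  P + 1,

giving exactly P + 2 attainable codes (26 for the default P = 24, R = 3).
Because thresholding depends only on the sign of intensity differences the
codes are invariant under positive affine grey-scale maps (and, when all
samples fall on pixel centres, under any strictly increasing transform;
with interpolated samples a nonlinear monotone map can flip near-tied
comparisons), and the popcount rule makes the code histogram rotation
invariant.

Neighbour i sits at ``(cx + R cos(2 pi i / P), cy - R sin(2 pi i / P))``
(y axis pointing down).  Pixels closer than ``ceil(R)`` to the ROI border
have no complete neighbourhood and are excluded rather than padded, so the
code matrix of an (h, w) ROI has shape ``(h - 2 ceil(R), w - 2 ceil(R))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import as_lifetime_matrix

__all__ = [
    "LBPParams",
    "LBPCodeMatrix",
    "LBPHistogram",
    "LBPFeatures",
    "sample_neighbors",
    "uniformity",
    "riu2_code",
    "lbp_transform",
    "lbp_histogram",
    "lbp_stats",
]

# offsets closer than this to a pixel centre are snapped onto it, so that
# axis-aligned samples reproduce the pixel value exactly
_SNAP = 1e-9


@dataclass(frozen=True)
class LBPParams:
    """Circular sampling geometry: P neighbours at radius R (pixels)."""

    P: int = 24
    R: float = 3.0

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError(f"P must be >= 4, got {self.P}")
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R}")

    @property
    def margin(self) -> int:
        return int(math.ceil(self.R))

    @property
    def n_codes(self) -> int:
        """Number of attainable riu2 codes: 0..P uniform plus one sentinel."""
        return self.P + 2


@dataclass(frozen=True)
class LBPCodeMatrix:
    """riu2 codes over the ROI interior (border of width ceil(R) excluded)."""

    codes: np.ndarray
    params: LBPParams

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.size == 0:
            raise ValueError("code matrix must be a non-empty 2-D array")
        if codes.min() < 0 or codes.max() > self.params.P + 1:
            raise ValueError("codes outside [0, P+1]")
        object.__setattr__(self, "codes", codes.astype(np.int64))


@dataclass(frozen=True)
class LBPHistogram:
    counts: np.ndarray  # length P+2, sums to number of valid pixels
    normalized: np.ndarray  # sums to 1


@dataclass(frozen=True)
class LBPFeatures:
    """Moment statistics of the code matrix + entropy of its 26-bin histogram."""

    mean: float
    sd: float
    skewness: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lbp_mean": self.mean,
            "lbp_sd": self.sd,
            "lbp_skewness": self.skewness,
            "lbp_entropy": self.entropy,
        }


def _circle_offsets(params: LBPParams) -> tuple[np.ndarray, np.ndarray]:
    """(dx, dy) sample offsets for neighbours 0..P-1, snapped to centres."""
    i = np.arange(params.P)
    theta = 2.0 * np.pi * i / params.P
    dx = params.R * np.cos(theta)
    dy = -params.R * np.sin(theta)
    dx = np.where(np.abs(dx - np.round(dx)) < _SNAP, np.round(dx), dx)
    dy = np.where(np.abs(dy - np.round(dy)) < _SNAP, np.round(dy), dy)
    return dx, dy


def _bilinear(m: np.ndarray, x: float, y: float) -> float:
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    tx, ty = x - x0, y - y0
    h, w = m.shape
    x1 = min(x0 + 1, w - 1) if tx == 0 else x0 + 1
    y1 = min(y0 + 1, h - 1) if ty == 0 else y0 + 1
    return float(
        (1 - tx) * (1 - ty) * m[y0, x0]
        + tx * (1 - ty) * m[y0, x1]
        + (1 - tx) * ty * m[y1, x0]
        + tx * ty * m[y1, x1]
    )


def sample_neighbors(m, cx: int, cy: int, params: LBPParams = LBPParams()) -> np.ndarray:
    """Bilinearly sample the P circular neighbours of pixel (cx, cy)."""
    m = as_lifetime_matrix(m)
    h, w = m.shape
    marg = params.margin
    if not (marg <= cx < w - marg and marg <= cy < h - marg):
        raise ValueError(f"circle of radius {params.R} around ({cx},{cy}) exits the matrix")
    dx, dy = _circle_offsets(params)
    return np.array([_bilinear(m, cx + ddx, cy + ddy) for ddx, ddy in zip(dx, dy)])


def _check_bits(bits) -> np.ndarray:
    b = np.asarray(bits)
    if b.ndim != 1 or not np.isin(b, (0, 1)).all():
        raise ValueError("bits must be a 1-D vector of 0/1")
    return b.astype(np.int64)


def uniformity(bits) -> int:
    """Circular 0<->1 transition count U of a binary neighbour pattern."""
    b = _check_bits(bits)
    return int(np.abs(b - np.roll(b, 1)).sum())


def riu2_code(bits) -> int:
    """popcount if the pattern is uniform (U <= 2), else the sentinel P+1."""
    b = _check_bits(bits)
    if uniformity(b) <= 2:
        return int(b.sum())
    return b.size + 1


def lbp_transform(roi, params: LBPParams = LBPParams()) -> LBPCodeMatrix:
    """riu2-transform a ROI; returns codes for the interior grid.

    Vectorised: each neighbour direction is one bilinear combination of four
    shifted views of the ROI, so the cost is O(P) array operations.
    """
    roi = as_lifetime_matrix(roi)
    if np.isnan(roi).any():
        raise ValueError("ROI contains NaN pixels")
    h, w = roi.shape
    marg = params.margin
    ih, iw = h - 2 * marg, w - 2 * marg
    if ih < 1 or iw < 1:
        raise ValueError(f"ROI {roi.shape} too small for radius {params.R} (needs > {2 * marg})")

    center = roi[marg : marg + ih, marg : marg + iw]
    dx, dy = _circle_offsets(params)
    bits = np.empty((params.P, ih, iw), dtype=np.int8)
    for i in range(params.P):
        fx, fy = math.floor(dx[i]), math.floor(dy[i])
        tx, ty = dx[i] - fx, dy[i] - fy
        # 4-tap bilinear stencil as shifted slices of the full ROI
        acc = np.zeros((ih, iw))
        for (oy, ox), wgt in (
            ((fy, fx), (1 - tx) * (1 - ty)),
            ((fy, fx + 1), tx * (1 - ty)),
            ((fy + 1, fx), (1 - tx) * ty),
            ((fy + 1, fx + 1), tx * ty),
        ):
            if wgt == 0.0:
                continue
            y0, x0 = marg + oy, marg + ox
            acc += wgt * roi[y0 : y0 + ih, x0 : x0 + iw]
        bits[i] = acc >= center

    transitions = np.abs(bits - np.roll(bits, 1, axis=0)).sum(axis=0)
    popcount = bits.sum(axis=0, dtype=np.int64)
    codes = np.where(transitions <= 2, popcount, params.P + 1)
    return LBPCodeMatrix(codes=codes, params=params)


def lbp_histogram(c: LBPCodeMatrix) -> LBPHistogram:
    """Counts of each riu2 code 0..P+1 over the valid region."""
    counts = np.bincount(c.codes.ravel(), minlength=c.params.n_codes)
    return LBPHistogram(counts=counts, normalized=counts / counts.sum())


def lbp_stats(c: LBPCodeMatrix, entropy_base="e") -> LBPFeatures:
    """Mean/SD/skewness of the code matrix and entropy of its histogram.

    The mean equals the frequency-weighted histogram index, so either
    reading of "LBP mean" gives the same number.
    """
    from .features import _base_value  # shared base handling

    v = c.codes.ravel().astype(float)
    sd = float(v.std(ddof=0))
    skew = float(sps.skew(v, bias=True)) if sd > 0 else 0.0
    hist = lbp_histogram(c)
    ent = float(sps.entropy(hist.counts, base=_base_value(entropy_base)))
    return LBPFeatures(mean=float(v.mean()), sd=sd, skewness=skew, entropy=ent)
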