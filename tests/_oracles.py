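"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (double loops, full enumeration) and
shares no code with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_riu2(img: np.ndarray, P: int, R: float) -> np.ndarray:
    """Naive per-pixel riu2 LBP with circular bilinear sampling.

    The sample position is expressed as integer base + fractional offset
    (the fraction taken from the circle offset itself, not from the
    absolute coordinate) so that sampling is translation invariant: every
    centre pixel sees bit-identical interpolation weights.
    """
    marg = math.ceil(R)
    h, w = img.shape
    offs = []
    for i in range(P):
        ang = 2 * math.pi * i / P
        dx, dy = R * math.cos(ang), -R * math.sin(ang)
        if abs(dx - round(dx)) < 1e-9:
            dx = round(dx)
        if abs(dy - round(dy)) < 1e-9:
            dy = round(dy)
        offs.append((dx, dy))
    out = np.zeros((h - 2 * marg, w - 2 * marg), dtype=int)
    for y in range(marg, h - marg):
        for x in range(marg, w - marg):
            gc = img[y, x]
            bits = []
            for dx, dy in offs:
                fx, fy = math.floor(dx), math.floor(dy)
                tx, ty = dx - fx, dy - fy
                x0, y0 = x + fx, y + fy
                gi = (
                    (1 - tx) * (1 - ty) * img[y0, x0]
                    + tx * (1 - ty) * img[y0, min(x0 + 1, w - 1)]
                    + (1 - tx) * ty * img[min(y0 + 1, h - 1), x0]
                    + tx * ty * img[min(y0 + 1, h - 1), min(x0 + 1, w - 1)]
                )
                bits.append(1 if gi >= gc else 0)
            u = sum(abs(bits[i] - bits[i - 1]) for i in range(P))
            out[y - marg, x - marg] = sum(bits) if u <= 2 else P + 1
    return out


def mw_exact_p(a, b) -> tuple[float, float]:
    """(U of sample a, exact two-sided p) by full permutation enumeration."""
    a, b = list(a), list(b)
    pooled = a + b
    n1, n2 = len(a), len(b)
    idx = range(len(pooled))

    def u_of(group_a) -> float:
        ga = [pooled[i] for i in group_a]
        gb = [pooled[i] for i in idx if i not in group_a]
        u = 0.0
        for x in ga:
            for y in gb:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(c) for c in itertools.combinations(idx, n1)]
    m = len(us)
    cdf = sum(1 for u in us if u <= u_obs) / m
    sf = sum(1 for u in us if u >= u_obs) / m
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_exact_p(diffs) -> tuple[float, float]:
    """(W+ statistic, exact two-sided p) by sign-pattern enumeration."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    absd = np.abs(d)
    ranks = np.argsort(np.argsort(absd)) + 1.0  # no ties expected by caller
    w_obs = float(ranks[np.asarray(d) > 0].sum())
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    m = len(ws)
    cdf = sum(1 for w in ws if w <= w_obs) / m
    sf = sum(1 for w in ws if w >= w_obs) / m
    return w_obs, min(1.0, 2.0 * min(cdf, sf))


def quantile_linear(values, q: float) -> float:
    """Linear-interpolation quantile computed from first principles."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
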