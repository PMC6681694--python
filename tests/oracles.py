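"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes the quantity by direct enumeration or plain Python
loops, sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sphere_offsets(spacing, target_volume_mL=1.0):
    """Integer voxel offsets with centers within the equivalent-sphere radius."""
    r = (3.0 * target_volume_mL * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    sz, sy, sx = spacing
    out = []
    nz, ny, nx = (int(r // s) for s in spacing)
    for dz in range(-nz, nz + 1):
        for dy in range(-ny, ny + 1):
            for dx in range(-nx, nx + 1):
                if (dz * sz) ** 2 + (dy * sy) ** 2 + (dx * sx) ** 2 <= r * r + 1e-9:
                    out.append((dz, dy, dx))
    return out or [(0, 0, 0)]


def brute_peak_sphere(values, mask, spacing, mode="max", target_volume_mL=1.0):
    """Exhaustive scan over all in-mask centers whose kernel fits in-bounds.

    Returns (value, center); None when no center admits the full kernel.
    """
    offs = sphere_offsets(spacing, target_volume_mL)
    shape = values.shape
    best, best_center = None, None
    for center in np.argwhere(mask):
        total, ok = 0.0, True
        for off in offs:
            p = (center[0] + off[0], center[1] + off[1], center[2] + off[2])
            if any(c < 0 or c >= s for c, s in zip(p, shape)):
                ok = False
                break
            total += values[p]
        if not ok:
            continue
        m = total / len(offs)
        if best is None or (mode == "max" and m > best) or (mode == "min" and m < best):
            best, best_center = m, tuple(int(c) for c in center)
    return (best, best_center) if best is not None else None


def brute_isocontour(values, mask, fraction):
    """Voxel-by-voxel threshold scan."""
    vmax = max(values[tuple(c)] for c in np.argwhere(mask))
    out = np.zeros_like(mask, dtype=bool)
    for c in np.argwhere(mask):
        if values[tuple(c)] >= fraction * vmax:
            out[tuple(c)] = True
    return out


def wilcoxon_exact_two_sided_p(diffs):
    """Enumerate all 2^n sign assignments of |diffs| (no zeros, no ties).

    Two-sided p = 2 * min(P(W+ <= w), P(W+ >= w)), capped at 1, with W+ the
    sum of ranks of positive differences.
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0) and np.unique(np.abs(d)).size == d.size
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(lo, hi))


def mwu_exact_two_sided_p(a, b):
    """Enumerate all C(n+m, n) group labelings of the pooled untied sample.

    U = number of (a, b) pairs with a > b.  Two-sided p = 2 * min tail,
    capped at 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size
    n = a.size

    def u_stat(x, y):
        return float(sum(1 for xi in x for yi in y if xi > yi))

    u_obs = u_stat(a, b)
    us = []
    idx = range(pooled.size)
    for comb in itertools.combinations(idx, n):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(comb)] = True
        us.append(u_stat(pooled[sel], pooled[~sel]))
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


def bh_brute(p_values, q):
    """Literal step-up definition: largest k with p_(k) <= k q / m; reject
    the k smallest p-values (ties with the cutoff included)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        cutoff = p[order[k_star - 1]]
        reject = p <= cutoff
    return reject
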