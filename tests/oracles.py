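"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, direct formulas) kept
separate from the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def trilinear_point(values: np.ndarray, idx: tuple[float, float, float]) -> float:
    """Direct 8-corner trilinear interpolation at one fractional index,
    clamping to the edge (matches nearest-edge extension inside support)."""
    out = 0.0
    base = [math.floor(c) for c in idx]
    frac = [c - b for c, b in zip(idx, base)]
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                ix = min(max(base[0] + dx, 0), values.shape[0] - 1)
                iy = min(max(base[1] + dy, 0), values.shape[1] - 1)
                iz = min(max(base[2] + dz, 0), values.shape[2] - 1)
                out += w * values[ix, iy, iz]
    return out


def dose_at_volume_bruteforce(doses: np.ndarray, voxel_cc: float, v_cc: float) -> float:
    """Sort voxels hottest-first, accumulate volume, interpolate at v_cc."""
    d = sorted(doses.tolist(), reverse=True)
    vols = [(k + 1) * voxel_cc for k in range(len(d))]
    if v_cc <= vols[0]:
        return d[0]
    for k in range(1, len(d)):
        if v_cc <= vols[k]:
            f = (v_cc - vols[k - 1]) / (vols[k] - vols[k - 1])
            return d[k - 1] + f * (d[k] - d[k - 1])
    return d[-1]


def volume_above_bruteforce(doses: np.ndarray, voxel_cc: float, threshold: float) -> float:
    return sum(1 for d in doses.tolist() if d >= threshold) * voxel_cc


def mean_bruteforce(doses: np.ndarray) -> float:
    return sum(doses.tolist()) / len(doses)


def paired_t_bruteforce(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Textbook paired t statistic and two-sided p via the t distribution."""
    from scipy.stats import t as t_dist

    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    sd = math.sqrt(sum((x - d.mean()) ** 2 for x in d) / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * t_dist.sf(abs(t), df=n - 1)
    return t, p
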