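"""Independent brute-force overlap oracle for the patternator tests.

Deliberately implemented with a different mechanism than the library
(per-groove dict accumulation in pure Python instead of vectorized array
slicing) so the two can cross-check each other: for each pass the (possibly
mirrored) profile grooves are dropped one by one into a dict keyed by grid
index, and the CV window is resolved in index space.
"""

from __future__ import annotations

import math


def brute_pattern(positions, volumes, pitch, swath, n_passes=7, mirrored=True):
    """Return (deposition dict keyed by grid index, window indices list)."""
    positions = list(map(float, positions))
    volumes = list(map(float, volumes))
    x0 = positions[0]
    total = sum(volumes)
    center = sum(p * v for p, v in zip(positions, volumes)) / total
    half_pitch = pitch / 2.0
    c_snap = round((center - x0) / half_pitch) * half_pitch + x0
    k_steps = round(swath / pitch)
    assert abs(k_steps * pitch - swath) < 1e-6 * pitch

    dep: dict[int, float] = {}
    half = (n_passes - 1) // 2
    for k in range(-half, half + 1):
        rev = mirrored and (k % 2 != 0)
        for p, v in zip(positions, volumes):
            x = (2.0 * c_snap - p) if rev else p
            x += k * swath
            idx = round((x - x0) / pitch)
            dep[idx] = dep.get(idx, 0.0) + v

    n_win = max(k_steps, 2)
    center_idx = (c_snap - x0) / pitch
    start = math.floor(center_idx - n_win / 2.0 + 0.5 + 1e-6)
    window = list(range(start, start + n_win))
    return dep, window


def brute_cv(positions, volumes, pitch, swath, n_passes=7, mirrored=True):
    dep, window = brute_pattern(positions, volumes, pitch, swath, n_passes, mirrored)
    vals = [dep.get(i, 0.0) for i in window]
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return sd / mean * 100.0


def brute_esw(positions, volumes, pitch, swaths, threshold=15.0,
              n_passes=7, mirrored=True):
    """(cvs list, effective swath width or None) over the given spacings."""
    cvs = [
        brute_cv(positions, volumes, pitch, s, n_passes, mirrored) for s in swaths
    ]
    compliant = [s for s, cv in zip(swaths, cvs) if cv < threshold]
    return cvs, (max(compliant) if compliant else None)
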