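"""Independent brute-force reference implementations used by the tests.

These deliberately use naive loops and standard-library containers so
they share no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))


def oracle_decorrelation(frames: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean Pearson correlation over every frame pair at each lag 0..max_lag."""
    n = frames.shape[0]
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        vals = [pearson(frames[i], frames[i + k]) for i in range(n - k)]
        out[k] = np.mean(vals)
    out[0] = 1.0
    return out


def oracle_tlasca(frames: np.ndarray) -> float:
    """Explicit per-pixel loop: temporal sample std over mean, spatial mean."""
    _, h, w = frames.shape
    ratios = []
    for r in range(h):
        for c in range(w):
            series = frames[:, r, c].astype(float)
            mu = series.mean()
            if mu == 0:
                continue
            sd = series.std(ddof=1)
            ratios.append(sd / mu)
    return float(np.mean(ratios))


def oracle_inertia_moment(frames: np.ndarray, levels: int, bit_depth: int) -> float:
    """Materialize the THSP matrix and count time-adjacent pairs in a dict."""
    t, h, w = frames.shape
    thsp = []
    for r in range(h):
        for c in range(w):
            row = []
            for i in range(t):
                q = int(frames[i, r, c]) * levels // (2**bit_depth)
                row.append(min(q, levels - 1))
            thsp.append(row)
    counts: dict[tuple[int, int], int] = {}
    for row in thsp:
        for a, b in zip(row[:-1], row[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    total = sum(counts.values())
    return sum(n * (i - j) ** 2 for (i, j), n in counts.items()) / total
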