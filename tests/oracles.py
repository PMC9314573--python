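"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive double loops and explicit enumeration and
share no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


def brute_force_measures(series, m, d, r, min_line=2):
    """Naive MdRQA: explicit loops over points, pairs and columns."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n, dims = arr.shape
    n_pts = n - (m - 1) * d
    points = []
    for t in range(n_pts):
        coords = []
        for k in range(m):
            coords.extend(arr[t + k * d])
        points.append(coords)

    rp = [[0] * n_pts for _ in range(n_pts)]
    for i in range(n_pts):
        for j in range(n_pts):
            dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(points[i], points[j])))
            rp[i][j] = 1 if dist <= r else 0

    n_rec = sum(sum(row) for row in rp)
    rec_pct = 100.0 * n_rec / (n_pts * n_pts)
    if n_rec == 0:
        return rec_pct, 0.0, 0.0, 0.0

    lam_count = 0
    for i in range(n_pts):
        for j in range(n_pts):
            if not rp[i][j]:
                continue
            above = i > 0 and rp[i - 1][j]
            below = i < n_pts - 1 and rp[i + 1][j]
            if above or below:
                lam_count += 1
    lam_pct = 100.0 * lam_count / n_rec

    lines = []
    for j in range(n_pts):
        run = 0
        for i in range(n_pts):
            if rp[i][j]:
                run += 1
            else:
                if run >= min_line:
                    lines.append(run)
                run = 0
        if run >= min_line:
            lines.append(run)
    if not lines:
        return rec_pct, lam_pct, 0.0, 0.0
    return rec_pct, lam_pct, float(np.mean(lines)), float(max(lines))


def wilcoxon_enumeration(diffs):
    """Exact two-sided signed-rank test by enumerating all sign vectors."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = rankdata(np.abs(diffs))
    t_plus = float(ranks[diffs > 0].sum())
    t_stat = min(t_plus, float(ranks.sum()) - t_plus)
    dist = []
    for signs in itertools.product((0, 1), repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.asarray(dist)
    p = 2 * min((dist <= t_plus).mean(), (dist >= t_plus).mean())
    return t_stat, min(1.0, float(p))
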