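"""Embedding-parameter estimation and radius calibration.

The delay is taken at the first local minimum of the multivariate average
mutual information (AMI) function; the embedding dimension where the
multivariate false-nearest-neighbor (FNN) fraction bottoms out.
Per-group estimates are pooled by averaging and rounding up, and a single
recurrence radius is calibrated so that the sample-mean recurrence rate
falls inside a target band (1-5 %REC by default).

Shipped defaults (used when no estimation is requested):
dyads d=2, m=7, r=0.457; triads d=2, m=7, r=0.51; Euclidean norm;
no input normalization.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .rqa import _as_2d, delay_embed, recurrence_rate_profile

__all__ = [
    "EmbeddingParams",
    "DYAD_DEFAULTS",
    "TRIAD_DEFAULTS",
    "multivariate_ami",
    "first_local_minimum",
    "multivariate_fnn",
    "select_dimension",
    "pool_parameters",
    "calibrate_threshold",
    "estimate_params",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters for one analysis level."""

    delay: int
    dimension: int
    radius: float
    norm: str = "euclidean"
    level: str = "triad"
    normalize_input: bool = False

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError(f"delay must be >= 1, got {self.delay}")
        if self.dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {self.dimension}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.norm != "euclidean":
            raise ValueError(f"unsupported norm: {self.norm!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EmbeddingParams":
        return cls(**d)


DYAD_DEFAULTS = EmbeddingParams(delay=2, dimension=7, radius=0.457, level="dyad")
TRIAD_DEFAULTS = EmbeddingParams(delay=2, dimension=7, radius=0.51, level="triad")


def multivariate_ami(series: np.ndarray, max_lag: int, n_bins: int | None = None) -> np.ndarray:
    """Average mutual information between a series and its lagged copy.

    MI is estimated per channel from an equal-width joint histogram and
    averaged over channels; returned for lags ``0..max_lag`` (nats).
    ``n_bins`` defaults to ``ceil(sqrt(N))``.
    """
    arr = _as_2d(series)
    n, dims = arr.shape
    if n <= max_lag + 1:
        raise ValueError(f"series length {n} must exceed max_lag + 1 = {max_lag + 1}")
    if n_bins is None:
        n_bins = int(math.ceil(math.sqrt(n)))
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    for k in range(dims):
        if np.ptp(arr[:, k]) == 0:
            raise ValueError(f"channel {k} is constant; mutual information undefined")

    ami = np.zeros(max_lag + 1)
    for k in range(dims):
        x = arr[:, k]
        edges = np.histogram_bin_edges(x, bins=n_bins)
        for lag in range(max_lag + 1):
            a = x[: n - lag]
            b = x[lag:]
            joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
            pxy = joint / joint.sum()
            px = pxy.sum(axis=1, keepdims=True)
            py = pxy.sum(axis=0, keepdims=True)
            nz = pxy > 0
            ami[lag] += float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    return ami / dims


def first_local_minimum(curve: Sequence[float]) -> int:
    """Index of the first local minimum of a curve, searching from lag 1.

    Ties break toward the smaller lag (``curve[i] <= curve[i-1]`` and
    ``curve[i] <= curve[i+1]``).  If no interior local minimum exists the
    global minimum over lags >= 1 is returned with a warning.
    """
    c = np.asarray(curve, dtype=float)
    if c.size < 3:
        raise ValueError(f"curve must have length >= 3, got {c.size}")
    for i in range(1, c.size - 1):
        if c[i] <= c[i - 1] and c[i] <= c[i + 1]:
            return i
    fallback = int(np.argmin(c[1:])) + 1
    warnings.warn(
        f"no local minimum found; falling back to global minimum at lag {fallback}",
        stacklevel=2,
    )
    return fallback


def multivariate_fnn(
    series: np.ndarray,
    delay: int,
    max_dim: int,
    rtol: float = 10.0,
    atol: float = 2.0,
) -> np.ndarray:
    """False-nearest-neighbor fractions for dimensions ``1..max_dim``.

    Kennel-style criteria on the multivariate embedding: a neighbor is
    false when the distance added by the next embedding dimension exceeds
    ``rtol`` times the current neighbor distance, or the expanded distance
    exceeds ``atol`` times the attractor size.
    """
    arr = _as_2d(series)
    n = arr.shape[0]
    if n - max_dim * delay < 10:
        raise ValueError(
            f"series length {n} too short for max_dim={max_dim}, delay={delay}"
        )
    attractor_size = float(np.sqrt(np.mean((arr - arr.mean(axis=0)) ** 2)))
    if attractor_size == 0:
        raise ValueError("constant series; FNN undefined")

    fractions = np.zeros(max_dim)
    for m in range(1, max_dim + 1):
        emb_m = delay_embed(arr, m=m, d=delay).points
        emb_m1 = delay_embed(arr, m=m + 1, d=delay).points
        n_valid = emb_m1.shape[0]
        pts = emb_m[:n_valid]
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=2)
        nn_dist = dist[:, 1]
        nn_idx = idx[:, 1]
        extra = np.linalg.norm(
            emb_m1[np.arange(n_valid), -arr.shape[1]:]
            - emb_m1[nn_idx, -arr.shape[1]:],
            axis=1,
        )
        expanded = np.sqrt(nn_dist**2 + extra**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(nn_dist > 0, extra / nn_dist, np.inf)
        false = (ratio > rtol) | (expanded / attractor_size > atol)
        fractions[m - 1] = float(false.mean())
    return fractions


def select_dimension(fnn_curve: Sequence[float], drop_tolerance: float = 0.01) -> int:
    """Dimension where the FNN curve bottoms out.

    The smallest ``m`` whose FNN fraction is below 0.05, or whose decrease
    to ``m + 1`` is at most ``drop_tolerance``, whichever comes first.
    """
    c = np.asarray(fnn_curve, dtype=float)
    if c.size == 0:
        raise ValueError("empty FNN curve")
    for m in range(1, c.size + 1):
        if c[m - 1] < 0.05:
            return m
        if m < c.size and c[m - 1] - c[m] <= drop_tolerance + 1e-12:
            return m
    return int(c.size)


def pool_parameters(per_group_estimates: Sequence[tuple[float, float]]) -> tuple[int, int]:
    """Pool (delay, dimension) estimates: component-wise mean, rounded up."""
    if len(per_group_estimates) == 0:
        raise ValueError("no estimates to pool")
    arr = np.asarray(per_group_estimates, dtype=float)
    means = arr.mean(axis=0)
    return int(math.ceil(means[0])), int(math.ceil(means[1]))


def calibrate_threshold(
    datasets: Sequence[np.ndarray],
    d: int,
    m: int,
    r_grid: Sequence[float] | None = None,
    band: tuple[float, float] = (1.0, 5.0),
) -> tuple[float, float]:
    """Smallest grid radius whose across-dataset mean %REC lies in ``band``.

    Returns ``(radius, achieved mean %REC)``.  Raises if no grid value
    lands inside the band, reporting the bracketing radii.
    """
    if len(datasets) == 0:
        raise ValueError("no datasets supplied")
    if r_grid is None:
        r_grid = np.arange(0.05, 1.0 + 1e-12, 0.005)
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0 or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be non-empty and strictly ascending")

    profiles = np.stack(
        [recurrence_rate_profile(ds, m=m, d=d, r_values=r_grid) for ds in datasets]
    )
    mean_rec = profiles.mean(axis=0)
    lo, hi = band
    in_band = (mean_rec >= lo) & (mean_rec <= hi)
    if not np.any(in_band):
        below = mean_rec[mean_rec < lo]
        above = mean_rec[mean_rec > hi]
        raise ValueError(
            "no grid radius yields mean %REC in "
            f"[{lo}, {hi}]: closest below = "
            f"{below.max() if below.size else None}, closest above = "
            f"{above.min() if above.size else None}; refine the grid"
        )
    i = int(np.argmax(in_band))
    return float(r_grid[i]), float(mean_rec[i])


def estimate_params(
    datasets: Sequence[np.ndarray],
    level: str,
    max_lag: int = 50,
    max_dim: int = 12,
    r_grid: Sequence[float] | None = None,
    n_bins: int | None = None,
    rtol: float = 10.0,
    atol: float = 2.0,
    normalize_input: bool = False,
) -> EmbeddingParams:
    """Full estimation pipeline over a sample of multivariate datasets.

    Per dataset: delay from the AMI first local minimum, dimension from
    the FNN curve at that delay.  Estimates are pooled (mean, rounded up)
    and the radius calibrated on the pooled embedding.
    """
    estimates = []
    for ds in datasets:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ami = multivariate_ami(ds, max_lag=max_lag, n_bins=n_bins)
            d_i = first_local_minimum(ami)
            fnn = multivariate_fnn(ds, delay=d_i, max_dim=max_dim, rtol=rtol, atol=atol)
        m_i = select_dimension(fnn)
        estimates.append((d_i, m_i))
    d, m = pool_parameters(estimates)
    if r_grid is None:
        r_grid = np.arange(0.005, 1.5, 0.005)  # wider than the calibration default
    r, _ = calibrate_threshold(datasets, d=d, m=m, r_grid=r_grid)
    return EmbeddingParams(
        delay=d, dimension=m, radius=r, level=level, normalize_input=normalize_input
    )
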