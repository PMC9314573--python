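"""Multidimensional recurrence quantification analysis (MdRQA) core.

A multivariate series (N samples x D channels) is delay-embedded into a
joint phase space of dimension ``D * m``, pairwise Euclidean distances are
thresholded at a radius ``r`` to form a binary recurrence plot, and the
plot is summarised by recurrence rate and vertical-line statistics.

Conventions (fixed for reproducibility):

* the threshold comparison is inclusive (``distance <= r``);
* the main diagonal (line of identity) is included in all measures and no
  Theiler window is applied;
* vertical lines are maximal runs of recurrent cells within a column of
  length >= ``min_line`` (default 2); isolated recurrent points do not
  count as lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PhaseTrajectory",
    "RecurrencePlot",
    "RecurrenceMeasures",
    "delay_embed",
    "distance_matrix",
    "recurrence_matrix",
    "vertical_line_lengths",
    "recurrence_measures",
    "mdrqa",
    "recurrence_rate_profile",
]


@dataclass(frozen=True)
class PhaseTrajectory:
    """Delay-embedded multivariate trajectory.

    ``points`` has shape ``(N - (m - 1) * d, D * m)`` where ``N`` is the
    input length and ``D`` the number of channels.
    """

    points: np.ndarray
    source_dims: int
    m: int
    d: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.points.shape[0]


@dataclass(frozen=True)
class RecurrencePlot:
    """Binary recurrence plot with the radius that produced it."""

    matrix: np.ndarray
    radius: float
    norm: str = "euclidean"

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class RecurrenceMeasures:
    """Recurrence-plot summary: %REC, %LAM, meanV, maxV."""

    rec_pct: float
    lam_pct: float
    mean_v: float
    max_v: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rec_pct": self.rec_pct,
            "lam_pct": self.lam_pct,
            "mean_v": self.mean_v,
            "max_v": self.max_v,
        }


def _as_2d(series: np.ndarray) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"series must be 1- or 2-dimensional, got ndim={arr.ndim}")
    return arr


def delay_embed(series: np.ndarray, m: int, d: int) -> PhaseTrajectory:
    """Time-delay embed an ``(N, D)`` series into ``D * m`` dimensions.

    Point ``t`` is the concatenation of rows ``t, t + d, ..., t + (m-1)d``.
    With ``m == 1`` the trajectory is exactly the input rows.
    """
    arr = _as_2d(series)
    if m < 1 or d < 1:
        raise ValueError(f"m and d must be positive integers, got m={m}, d={d}")
    n, dims = arr.shape
    span = (m - 1) * d
    if n < span + 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, d={d}; "
            f"requires at least {span + 1} samples"
        )
    n_points = n - span
    cols = [arr[k * d : k * d + n_points] for k in range(m)]
    points = np.concatenate(cols, axis=1)
    return PhaseTrajectory(points=points, source_dims=dims, m=m, d=d)


def distance_matrix(traj: PhaseTrajectory | np.ndarray) -> np.ndarray:
    """Square matrix of pairwise Euclidean distances between trajectory points."""
    pts = traj.points if isinstance(traj, PhaseTrajectory) else _as_2d(traj)
    if pts.shape[0] == 0:
        raise ValueError("trajectory has no points")
    if pts.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts, metric="euclidean"))


def recurrence_matrix(dist: np.ndarray, r: float) -> RecurrencePlot:
    """Threshold a distance matrix at radius ``r`` (inclusive)."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    dist = np.asarray(dist, dtype=float)
    return RecurrencePlot(matrix=(dist <= r), radius=float(r))


def vertical_line_lengths(rp: RecurrencePlot | np.ndarray, min_line: int = 2) -> np.ndarray:
    """Lengths of maximal vertical runs of recurrent cells, per column.

    Only runs of length >= ``min_line`` are returned; the main diagonal
    participates in runs like any other cell.
    """
    mat = rp.matrix if isinstance(rp, RecurrencePlot) else np.asarray(rp)
    mat = mat.astype(bool)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("recurrence plot must be a square matrix")
    # pad each column with zeros, then flatten column-major so every run
    # stays within one column and starts/ends pair up positionally
    padded = np.zeros((mat.shape[0] + 2, mat.shape[1]), dtype=np.int8)
    padded[1:-1] = mat
    flat = padded.T.reshape(-1)
    diff = np.diff(flat)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    lengths = ends - starts
    return lengths[lengths >= min_line]


def recurrence_measures(rp: RecurrencePlot | np.ndarray, min_line: int = 2) -> RecurrenceMeasures:
    """Compute %REC, %LAM, meanV and maxV for a recurrence plot."""
    mat = rp.matrix if isinstance(rp, RecurrencePlot) else np.asarray(rp)
    mat = mat.astype(bool)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("recurrence plot must be a square matrix")
    n = mat.shape[0]
    n_rec = int(mat.sum())
    rec_pct = 100.0 * n_rec / (n * n)

    if n_rec == 0:
        return RecurrenceMeasures(rec_pct, 0.0, 0.0, 0.0)

    has_neighbor = np.zeros_like(mat)
    has_neighbor[1:] |= mat[:-1]
    has_neighbor[:-1] |= mat[1:]
    lam_pct = 100.0 * int((mat & has_neighbor).sum()) / n_rec

    lines = vertical_line_lengths(mat, min_line=min_line)
    if lines.size == 0:
        return RecurrenceMeasures(rec_pct, lam_pct, 0.0, 0.0)
    return RecurrenceMeasures(
        rec_pct=rec_pct,
        lam_pct=lam_pct,
        mean_v=float(lines.mean()),
        max_v=float(lines.max()),
    )


def mdrqa(
    series: np.ndarray,
    m: int,
    d: int,
    r: float,
    min_line: int = 2,
    normalize_input: bool = False,
) -> RecurrenceMeasures:
    """End-to-end MdRQA: embed, threshold, quantify.

    ``normalize_input`` z-scores each channel before embedding; it is off
    by default (the analysis operates on raw interbeat intervals).
    """
    arr = _as_2d(series)
    if normalize_input:
        sd = arr.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("cannot normalize a constant channel")
        arr = (arr - arr.mean(axis=0)) / sd
    traj = delay_embed(arr, m=m, d=d)
    rp = recurrence_matrix(distance_matrix(traj), r)
    return recurrence_measures(rp, min_line=min_line)


def recurrence_rate_profile(series: np.ndarray, m: int, d: int, r_values: np.ndarray) -> np.ndarray:
    """%REC for each radius in ``r_values``, computed from one distance pass.

    Exploits that %REC is a step function of the sorted pairwise
    distances: much cheaper than re-thresholding per radius.
    """
    traj = delay_embed(_as_2d(series), m=m, d=d)
    n = len(traj)
    if n == 1:
        return np.full(len(r_values), 100.0)
    dists = np.sort(pdist(traj.points, metric="euclidean"))
    r_values = np.asarray(r_values, dtype=float)
    # inclusive threshold: pairs with distance <= r
    counts = np.searchsorted(dists, r_values, side="right")
    return 100.0 * (n + 2.0 * counts) / (n * n)
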