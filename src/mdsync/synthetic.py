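"""Synthetic study generator with tunable within-group coupling.

Each participant-phase IBI series is a stationary mean-reverting process

    IBI_t = mu_i + sd * (w * Z_t + sqrt(1 - w^2) * U_{i,t})

where ``Z`` is a latent AR(1) driver (coefficient ``driver_ar``, unit
stationary variance) shared by the members of a group within a phase,
``U_i`` is an idiosyncratic unit-variance AR(1) with coefficient
``ar_coefficient``, and ``sd = noise_sd / sqrt(1 - ar_coefficient^2)``
is the stationary SD the plain AR(1) would have.  The mixing weight
``w = kappa_p / sqrt(kappa_p^2 + noise_sd^2)`` maps the phase coupling
strength ``kappa_p`` onto [0, 1) so that coupling changes the
cross-member correlation without inflating the marginal variance --
coupled and uncoupled series stay on the same scale, which is what lets
a single fixed recurrence radius compare phases.  Series lengths are
drawn independently per participant-phase so downstream trimming is
always exercised.

Cohesion is generated per participant as a linear function of their
synchrony change score (task minus baseline), plus a condition offset, a
group random intercept and residual noise, clipped to the 1-6 scale of
the instrument.

All randomness derives from one integer seed via documented stream
splitting: ``default_rng([seed, stream, index])`` with stream 0 for IBI
generation (index = group) and stream 1 for cohesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import PHASES, GroupRecord, IBISeries

__all__ = [
    "SimConfig",
    "CohesionRecord",
    "StudyDataset",
    "generate_triad",
    "generate_cohesion",
    "generate_study",
]

DEFAULT_LAYOUT = (("1", "A", 23), ("1", "B", 22), ("2", "C", 21), ("2", "D", 21))
DEFAULT_CONDITION_EFFECTS = {"A": 0.0, "B": 0.15, "C": -0.15, "D": 0.0}


@dataclass(frozen=True)
class SimConfig:
    n_groups: int = 87
    members_per_group: int = 3
    condition_layout: tuple[tuple[str, str, int], ...] = DEFAULT_LAYOUT
    length_range: tuple[int, int] = (280, 400)
    ibi_mean_range: tuple[float, float] = (0.75, 0.95)
    ar_coefficient: float = 0.8
    coupling_baseline: float = 0.0
    coupling_task: float = 0.0
    noise_sd: float = 0.02
    driver_ar: float = 0.9
    cohesion_mean: float = 4.0
    cohesion_beta: float = 0.0
    condition_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS)
    )
    group_intercept_sd: float = 0.3
    residual_sd: float = 0.5
    ibi_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        layout_total = sum(n for _, _, n in self.condition_layout)
        if layout_total != self.n_groups:
            raise ValueError(
                f"condition_layout totals {layout_total} groups but n_groups={self.n_groups}"
            )
        if self.members_per_group != 3:
            raise ValueError("only triads (members_per_group=3) are supported")
        if not (0.0 < self.ar_coefficient < 1.0):
            raise ValueError(f"ar_coefficient must be in (0, 1), got {self.ar_coefficient}")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.ibi_mean_range[0] <= 0:
            raise ValueError("ibi_mean_range must be positive")
        if self.noise_sd < 0 or self.ibi_floor <= 0:
            raise ValueError("noise_sd must be >= 0 and ibi_floor > 0")

    def group_labels(self, group_index: int) -> tuple[str, str]:
        """(study, condition) for a group index, walking the layout blocks."""
        if not 0 <= group_index < self.n_groups:
            raise ValueError(f"group_index {group_index} out of range [0, {self.n_groups})")
        offset = 0
        for study, condition, n in self.condition_layout:
            if group_index < offset + n:
                return study, condition
            offset += n
        raise AssertionError("unreachable")  # layout validated in __post_init__


@dataclass(frozen=True)
class CohesionRecord:
    group_id: str
    member_id: int
    study: str
    condition: str
    cohesion: float


def _unit_ar(n: int, ar: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sample with unit variance (stationary start)."""
    innov_sd = np.sqrt(1.0 - ar**2)
    z = np.empty(n)
    z[0] = rng.normal()
    z[1:] = innov_sd * rng.normal(size=n - 1)
    return lfilter([1.0], [1.0, -ar], z)


def _coupling_weight(kappa: float, sigma: float) -> float:
    if kappa == 0:
        return 0.0
    if sigma == 0:
        return 1.0
    return kappa / np.sqrt(kappa**2 + sigma**2)


def generate_triad(
    config: SimConfig, group_index: int, rng: np.random.Generator | None = None
) -> GroupRecord:
    """Generate one triad: 3 members x 2 phases of IBI series.

    ``coupling_baseline`` / ``coupling_task`` mix the shared phase driver
    into every member's fluctuations (variance-preserving, see module
    docstring).  Generated values are clipped from below at ``ibi_floor``
    to keep them strictly positive.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 0, group_index])
    study, condition = config.group_labels(group_index)
    gid = f"g{group_index + 1:03d}"
    phi = config.ar_coefficient
    lo, hi = config.length_range
    sd_m = config.noise_sd / np.sqrt(1.0 - phi**2)

    mus = rng.uniform(*config.ibi_mean_range, size=3)
    series: dict[tuple[int, str], IBISeries] = {}
    for phase, kappa in zip(PHASES, (config.coupling_baseline, config.coupling_task)):
        w = _coupling_weight(kappa, config.noise_sd)
        lengths = rng.integers(lo, hi + 1, size=3)
        driver = _unit_ar(int(lengths.max()), config.driver_ar, rng)
        for mem in range(3):
            n = int(lengths[mem])
            idio = _unit_ar(n, phi, rng)
            dev = sd_m * (w * driver[:n] + np.sqrt(1.0 - w**2) * idio)
            values = np.maximum(mus[mem] + dev, config.ibi_floor)
            series[(mem + 1, phase)] = IBISeries(
                values=values,
                group_id=gid,
                member_id=mem + 1,
                phase=phase,
                study=study,
                condition=condition,
            )
    return GroupRecord(group_id=gid, study=study, condition=condition, series=series)


def generate_cohesion(
    groups: Sequence[GroupRecord],
    delta_syncs: Mapping[tuple[str, int], float],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[CohesionRecord]:
    """Per-participant cohesion from the mixed-effects generating model.

    ``cohesion = mean + condition_effect + beta * delta + u_group + eps``,
    clipped to [1, 6].  ``delta_syncs`` maps ``(group_id, member_id)`` to
    that participant's synchrony change score.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    records: list[CohesionRecord] = []
    for group in groups:
        u = rng.normal(0.0, config.group_intercept_sd) if config.group_intercept_sd else 0.0
        cond_effect = config.condition_effects.get(group.condition, 0.0)
        for mid in group.member_ids:
            key = (group.group_id, mid)
            if key not in delta_syncs:
                raise KeyError(
                    f"no delta-sync value for participant group={group.group_id} member={mid}"
                )
            eps = rng.normal(0.0, config.residual_sd) if config.residual_sd else 0.0
            value = (
                config.cohesion_mean
                + cond_effect
                + config.cohesion_beta * delta_syncs[key]
                + u
                + eps
            )
            records.append(
                CohesionRecord(
                    group_id=group.group_id,
                    member_id=mid,
                    study=group.study,
                    condition=group.condition,
                    cohesion=float(np.clip(value, 1.0, 6.0)),
                )
            )
    return records


@dataclass(frozen=True)
class StudyDataset:
    """A complete synthetic study: triads plus per-participant cohesion."""

    groups: list[GroupRecord]
    cohesion: list[CohesionRecord]
    delta_syncs: dict[tuple[str, int], float]

    def ibi_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for (mid, phase), s in sorted(g.series.items()):
                rows.append(
                    pd.DataFrame(
                        {
                            "group_id": g.group_id,
                            "member_id": mid,
                            "study": g.study,
                            "condition": g.condition,
                            "phase": phase,
                            "beat_index": np.arange(len(s)),
                            "ibi_s": s.values,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def cohesion_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.cohesion])

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        """Write ``ibi.csv`` and ``cohesion.csv`` (deterministic formatting)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ibi_path = out_dir / "ibi.csv"
        coh_path = out_dir / "cohesion.csv"
        self.ibi_frame().to_csv(ibi_path, index=False, float_format="%.6f")
        self.cohesion_frame().to_csv(coh_path, index=False, float_format="%.6f")
        return ibi_path, coh_path


def generate_study(config: SimConfig, delta_source: str = "pipeline") -> StudyDataset:
    """Generate all triads and their cohesion outcomes.

    ``delta_source`` controls the synchrony change score fed into the
    cohesion model: ``'pipeline'`` runs the individual-level recurrence
    pipeline at the shipped dyad parameters (slow but end-to-end);
    ``'latent'`` draws standard-normal scores directly (fast, for
    simulations that only exercise the outcome model).
    """
    groups = [generate_triad(config, i) for i in range(config.n_groups)]

    if delta_source == "pipeline":
        from .sync import individual_delta_syncs

        delta_syncs = individual_delta_syncs(groups)
    elif delta_source == "latent":
        rng = np.random.default_rng([config.seed, 2])
        delta_syncs = {
            (g.group_id, mid): float(rng.normal()) for g in groups for mid in g.member_ids
        }
    else:
        raise ValueError(f"unknown delta_source {delta_source!r}")

    cohesion = generate_cohesion(groups, delta_syncs, config)
    return StudyDataset(groups=groups, cohesion=cohesion, delta_syncs=dict(delta_syncs))
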