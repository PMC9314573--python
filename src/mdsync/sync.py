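"""Group- and individual-level synchrony scoring, composites and surrogates.

Group-level synchrony subjects all three members' series jointly to
MdRQA.  Individual-level synchrony averages, for each member, the
recurrence measures of that member's two dyads within the triad.  The
Vertical Synchrony composite averages the z-scores of %LAM, meanV and
maxV across units of a stratum (level x phase); the change score
(``delta``) is the task composite minus the baseline composite.

False-pair surrogates re-combine members from three distinct real groups
into pseudo-triads; they are scored with the same parameters as real
groups, standardized against the real units' mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .embedding import DYAD_DEFAULTS, TRIAD_DEFAULTS, EmbeddingParams
from .preprocess import GroupRecord, IBISeries, assemble_level_inputs
from .rqa import RecurrenceMeasures, mdrqa

__all__ = [
    "SyncScore",
    "DeltaSync",
    "COMPOSITE_MEASURES",
    "group_level_sync",
    "individual_level_sync",
    "vertical_sync_composite",
    "delta_sync",
    "false_pair_surrogates",
    "score_study",
    "individual_delta_syncs",
]

COMPOSITE_MEASURES = ("lam_pct", "mean_v", "max_v")


@dataclass(frozen=True)
class SyncScore:
    unit_id: str
    level: str  # "group" | "individual"
    phase: str
    measures: RecurrenceMeasures
    vertical_sync: float | None = None
    is_surrogate: bool = False


@dataclass(frozen=True)
class DeltaSync:
    unit_id: str
    level: str
    delta: float
    measure_deltas: dict[str, float]
    is_surrogate: bool = False


def _run_mdrqa(array: np.ndarray, params: EmbeddingParams) -> RecurrenceMeasures:
    return mdrqa(
        array,
        m=params.dimension,
        d=params.delay,
        r=params.radius,
        normalize_input=params.normalize_input,
    )


def group_level_sync(
    group: GroupRecord, params: EmbeddingParams = TRIAD_DEFAULTS, phase: str = "task"
) -> SyncScore:
    """One score per triad from the joint 3-channel MdRQA."""
    ((_, array),) = assemble_level_inputs(group, level="triad", phase=phase)
    return SyncScore(
        unit_id=group.group_id,
        level="group",
        phase=phase,
        measures=_run_mdrqa(array, params),
        is_surrogate=group.is_surrogate,
    )


def individual_level_sync(
    group: GroupRecord, params: EmbeddingParams = DYAD_DEFAULTS, phase: str = "task"
) -> list[SyncScore]:
    """Three scores per triad: each member's mean over its two dyads."""
    dyads = assemble_level_inputs(group, level="dyad", phase=phase)
    dyad_measures = {pair: _run_mdrqa(array, params) for pair, array in dyads}
    scores = []
    for member in group.member_ids:
        own = [m for pair, m in dyad_measures.items() if member in pair]
        assert len(own) == 2
        mean = RecurrenceMeasures(
            **{
                k: float(np.mean([m.as_dict()[k] for m in own]))
                for k in ("rec_pct", "lam_pct", "mean_v", "max_v")
            }
        )
        scores.append(
            SyncScore(
                unit_id=f"{group.group_id}:{member}",
                level="individual",
                phase=phase,
                measures=mean,
                is_surrogate=group.is_surrogate,
            )
        )
    return scores


def vertical_sync_composite(scores: Sequence[SyncScore]) -> list[SyncScore]:
    """Fill ``vertical_sync`` as the mean z-score of %LAM, meanV, maxV.

    Standardization is within each (level, phase) stratum over real
    (non-surrogate) units; surrogate units are scored against the real
    units' mean and SD so they remain on a comparable scale.
    """
    out = list(scores)
    strata = sorted({(s.level, s.phase) for s in scores})
    for level, phase in strata:
        idx = [i for i, s in enumerate(out) if (s.level, s.phase) == (level, phase)]
        ref = [i for i in idx if not out[i].is_surrogate] or idx
        if len(ref) < 2:
            raise ValueError(
                f"stratum level={level} phase={phase} needs >= 2 reference units"
            )
        stats = {}
        for name in COMPOSITE_MEASURES:
            vals = np.array([getattr(out[i].measures, name) for i in ref])
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(
                    f"measure {name!r} has zero variance in stratum "
                    f"level={level} phase={phase}"
                )
            stats[name] = (vals.mean(), sd)
        for i in idx:
            zs = [
                (getattr(out[i].measures, name) - mu) / sd
                for name, (mu, sd) in stats.items()
            ]
            out[i] = replace(out[i], vertical_sync=float(np.mean(zs)))
    return out


def delta_sync(
    task_scores: Sequence[SyncScore], baseline_scores: Sequence[SyncScore]
) -> list[DeltaSync]:
    """Task minus baseline, per unit, for the composite and each measure."""
    base = {s.unit_id: s for s in baseline_scores}
    task = {s.unit_id: s for s in task_scores}
    unmatched = sorted(set(base) ^ set(task))
    if unmatched:
        raise ValueError(f"unmatched unit ids across phases: {unmatched}")
    deltas = []
    for uid, t in task.items():
        b = base[uid]
        if t.vertical_sync is None or b.vertical_sync is None:
            raise ValueError(f"unit {uid}: composite not computed before delta")
        deltas.append(
            DeltaSync(
                unit_id=uid,
                level=t.level,
                delta=t.vertical_sync - b.vertical_sync,
                measure_deltas={
                    k: t.measures.as_dict()[k] - b.measures.as_dict()[k]
                    for k in t.measures.as_dict()
                },
                is_surrogate=t.is_surrogate,
            )
        )
    return deltas


def false_pair_surrogates(
    groups: Sequence[GroupRecord],
    n_surrogates: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[GroupRecord]:
    """Pseudo-triads pairing members drawn from three distinct real groups.

    Source groups are sampled without replacement within a pseudo-triad
    and with replacement across pseudo-triads; one member (both phases)
    is taken from each source group.  Defaults to as many surrogates as
    real groups.
    """
    real = [g for g in groups if not g.is_surrogate]
    if len(real) < 3:
        raise ValueError(f"need >= 3 real groups to form surrogates, got {len(real)}")
    if n_surrogates is None:
        n_surrogates = len(real)
    if rng is None:
        rng = np.random.default_rng()

    surrogates = []
    for k in range(n_surrogates):
        sources = rng.choice(len(real), size=3, replace=False)
        sid = f"s{k + 1:03d}"
        series: dict[tuple[int, str], IBISeries] = {}
        for new_mid, gi in enumerate(sources, start=1):
            src = real[int(gi)]
            member = int(rng.choice(src.member_ids))
            for phase in ("baseline", "task"):
                s = src.member_phase(member, phase)
                series[(new_mid, phase)] = replace(
                    s, group_id=sid, member_id=new_mid
                )
        surrogates.append(
            GroupRecord(
                group_id=sid,
                study="surrogate",
                condition="surrogate",
                series=series,
                is_surrogate=True,
            )
        )
    return surrogates


def score_study(
    groups: Sequence[GroupRecord],
    level: str = "group",
    phases: Sequence[str] = ("baseline", "task"),
    params: EmbeddingParams | None = None,
) -> list[SyncScore]:
    """Raw synchrony scores (no composite) for many groups and phases."""
    if params is None:
        params = TRIAD_DEFAULTS if level == "group" else DYAD_DEFAULTS
    scores: list[SyncScore] = []
    for phase in phases:
        for g in groups:
            if level == "group":
                scores.append(group_level_sync(g, params, phase))
            elif level == "individual":
                scores.extend(individual_level_sync(g, params, phase))
            else:
                raise ValueError(f"unknown level {level!r}")
    return scores


def calibrated_params(
    groups: Sequence[GroupRecord],
    level: str,
    d: int = 2,
    m: int = 7,
    r_grid: np.ndarray | None = None,
) -> EmbeddingParams:
    """Table-style parameters with the radius calibrated on this sample.

    Pools baseline and task datasets at the given level and picks the
    smallest grid radius whose sample-mean %REC is in the 1-5% band.
    """
    from .embedding import calibrate_threshold

    unit = "triad" if level == "group" else "dyad"
    datasets = [
        arr
        for g in groups
        for phase in ("baseline", "task")
        for _, arr in assemble_level_inputs(g, unit, phase)
    ]
    if r_grid is None:
        r_grid = np.arange(0.005, 1.5, 0.005)
    r, _ = calibrate_threshold(datasets, d=d, m=m, r_grid=r_grid)
    return EmbeddingParams(delay=d, dimension=m, radius=r, level=unit)


def individual_delta_syncs(
    groups: Sequence[GroupRecord], params: EmbeddingParams | None = None
) -> dict[tuple[str, int], float]:
    """Per-participant composite delta: the pipeline behind the outcome model.

    When ``params`` is omitted the dyad radius is calibrated on the
    sample (the shipped defaults describe the original data's scale, not
    an arbitrary synthetic study's).
    """
    if params is None:
        params = calibrated_params(groups, level="individual")
    scores = vertical_sync_composite(score_study(groups, level="individual", params=params))
    task = [s for s in scores if s.phase == "task"]
    base = [s for s in scores if s.phase == "baseline"]
    out = {}
    for ds in delta_sync(task, base):
        gid, mid = ds.unit_id.rsplit(":", 1)
        out[(gid, int(mid))] = ds.delta
    return out
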