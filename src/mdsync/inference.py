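"""Statistical stage: signed-rank contrasts and mixed-effects models.

Contrasts compare group-level recurrence rates between real and
false-pair pseudo-groups and between phases, with Wilcoxon signed-rank
tests (exact below 26 informative pairs).  The outcome model is a linear
mixed model predicting cohesion from the synchrony change score, the
4-level condition factor and their interaction, with a random intercept
per group; nested models are compared with a likelihood-ratio test on
maximum-likelihood refits.

Fixed-effect F-tests use Wald statistics with between-within denominator
degrees of freedom (group-constant terms are tested against the number
of groups minus the between-group parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sync import DeltaSync, SyncScore

__all__ = [
    "ModelFit",
    "TermTest",
    "wilcoxon_signed_rank",
    "fit_cohesion_model",
    "compare_levels",
    "run_contrasts",
    "build_model_frame",
]


@dataclass(frozen=True)
class TermTest:
    f_stat: float
    num_df: int
    den_df: float
    p_value: float


@dataclass(frozen=True)
class ModelFit:
    params: dict[str, float]
    bse: dict[str, float]
    term_tests: dict[str, TermTest]
    group_var: float
    resid_var: float
    marginal_r2: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    reml: bool
    formula: str = field(default="", compare=False)


def wilcoxon_signed_rank(paired_values: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on (a, b) pairs.

    Returns ``(T, p)`` where ``T`` is the smaller of the two signed-rank
    sums.  Zero differences are dropped; an exact p-value is used below
    26 informative pairs (asymptotic with ties or larger n).
    """
    arr = np.asarray(paired_values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("paired_values must be a sequence of (a, b) pairs")
    diff = arr[:, 0] - arr[:, 1]
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        raise ValueError("all pairs are tied; signed-rank test undefined")
    ranks = stats.rankdata(np.abs(diff))
    t_plus = float(ranks[diff > 0].sum())
    t_minus = float(ranks[diff < 0].sum())
    t_stat = min(t_plus, t_minus)
    has_ties = np.unique(np.abs(diff)).size < n
    method = "exact" if (n < 26 and not has_ties) else "approx"
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided", method=method)
    return t_stat, float(res.pvalue)


def build_model_frame(
    cohesion: pd.DataFrame,
    deltas: Sequence[DeltaSync] | Mapping,
    level: str,
) -> pd.DataFrame:
    """Join per-participant cohesion rows with a delta-sync predictor.

    ``level='group'`` joins by group id (every member of a triad shares
    the triadic delta); ``level='individual'`` joins by participant.
    """
    df = cohesion.copy()
    required = {"group_id", "member_id", "condition", "cohesion"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohesion table must have columns {sorted(required)}")
    if isinstance(deltas, Mapping):
        lookup = dict(deltas)
    else:
        lookup = {d.unit_id: d.delta for d in deltas}

    def key(row) -> str:
        if level == "group":
            return str(row.group_id)
        if level == "individual":
            return f"{row.group_id}:{row.member_id}"
        raise ValueError(f"unknown level {level!r}")

    keys = [key(r) for r in df.itertuples()]
    missing = sorted({k for k in keys if k not in lookup})
    if missing:
        raise ValueError(f"no delta-sync value for units: {missing[:10]}")
    df["delta"] = [lookup[k] for k in keys]
    df["group_id"] = df["group_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    return df


def _between_within_df(exog: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Flag which design columns are constant within every group."""
    frame = pd.DataFrame(exog)
    frame["_g"] = groups
    nunique = frame.groupby("_g").agg(lambda c: c.round(12).nunique())
    between = (nunique <= 1).all(axis=0).to_numpy()
    return between, int(between.sum()), int(len(between) - between.sum())


def _robust_fit(model, reml: bool):
    """Fit a MixedLM, falling back across optimizers on numerical failure."""
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=reml, method=method)
        except (np.linalg.LinAlgError, ValueError) as err:  # singular step
            last_err = err
    raise RuntimeError(f"mixed model failed to converge: {last_err}")


def fit_cohesion_model(
    cohesion: pd.DataFrame,
    deltas: Sequence[DeltaSync] | Mapping,
    level: str = "group",
    include_interaction: bool = True,
    reml: bool = True,
    random_by: str = "group",
) -> ModelFit:
    """REML fit of ``cohesion ~ delta * condition`` with a random intercept.

    ``random_by='group'`` (default) puts the intercept on the triad;
    ``random_by='study'`` on the study label instead.  Reports Wald
    F-tests per term with between-within denominator df, variance
    components and the marginal (fixed-effects) R-squared.
    """
    import statsmodels.formula.api as smf

    df = build_model_frame(cohesion, deltas, level)
    rhs = "delta * C(condition)" if include_interaction else "delta + C(condition)"
    formula = f"cohesion ~ {rhs}"
    if random_by == "group":
        group_col = df["group_id"]
    elif random_by == "study":
        if "study" not in df.columns:
            raise ValueError("cohesion table has no 'study' column")
        group_col = df["study"].astype(str)
    else:
        raise ValueError(f"unknown random_by {random_by!r}")

    model = smf.mixedlm(formula, df, groups=group_col)
    result = _robust_fit(model, reml=reml)

    fe_names = list(model.exog_names)
    k = len(fe_names)
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[:k, :k]
    n_obs = int(model.nobs)
    groups = group_col.to_numpy()
    n_groups = int(pd.unique(groups).size)

    between_cols, p_between, p_within = _between_within_df(model.exog, groups)
    den_between = max(n_groups - p_between, 1)
    den_within = max(n_obs - n_groups - p_within, 1)

    design_info = model.data.design_info
    term_tests: dict[str, TermTest] = {}
    for term in design_info.terms:
        if term.name() == "Intercept":
            continue
        sl = design_info.term_name_slices[term.name()]
        idx = np.arange(k)[sl]
        q = len(idx)
        b = beta[idx]
        v = cov[np.ix_(idx, idx)]
        f_stat = float(b @ np.linalg.solve(v, b)) / q
        den = den_between if bool(between_cols[idx].all()) else den_within
        p = float(stats.f.sf(f_stat, q, den))
        term_tests[term.name()] = TermTest(f_stat=f_stat, num_df=q, den_df=float(den), p_value=p)

    fitted_fixed = model.exog @ beta
    group_var = float(np.asarray(result.cov_re)[0, 0]) if result.cov_re.size else 0.0
    resid_var = float(result.scale)
    var_fixed = float(np.var(fitted_fixed))
    marginal_r2 = var_fixed / (var_fixed + group_var + resid_var)

    return ModelFit(
        params={name: float(b) for name, b in zip(fe_names, beta)},
        bse={name: float(s) for name, s in zip(fe_names, np.sqrt(np.diag(cov)))},
        term_tests=term_tests,
        group_var=group_var,
        resid_var=resid_var,
        marginal_r2=marginal_r2,
        llf=float(result.llf),
        n_obs=n_obs,
        n_groups=n_groups,
        converged=bool(result.converged),
        reml=reml,
        formula=formula,
    )


def compare_levels(
    cohesion: pd.DataFrame,
    individual_deltas: Sequence[DeltaSync] | Mapping,
    group_deltas: Sequence[DeltaSync] | Mapping,
    include_interaction: bool = False,
) -> tuple[float, int, float]:
    """LRT of adding the group-level delta to the individual-level model.

    Both models are refit by maximum likelihood.  If the group-level
    predictor is numerically collinear with the individual-level design,
    the statistic is 0 by construction.  Returns ``(chi2, df, p)``.
    """
    import statsmodels.formula.api as smf

    df = build_model_frame(cohesion, individual_deltas, level="individual")
    df = df.rename(columns={"delta": "ind_delta"})
    df_g = build_model_frame(cohesion, group_deltas, level="group")
    df["grp_delta"] = df_g["delta"].to_numpy()

    rhs = "ind_delta * C(condition)" if include_interaction else "ind_delta + C(condition)"
    reduced_f = f"cohesion ~ {rhs}"
    full_f = f"{reduced_f} + grp_delta"

    reduced = smf.mixedlm(reduced_f, df, groups=df["group_id"])
    full = smf.mixedlm(full_f, df, groups=df["group_id"])
    if np.linalg.matrix_rank(full.exog) <= np.linalg.matrix_rank(reduced.exog):
        return 0.0, 1, 1.0

    res_r = _robust_fit(reduced, reml=False)
    res_f = _robust_fit(full, reml=False)
    chi2 = max(0.0, 2.0 * (float(res_f.llf) - float(res_r.llf)))
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, 1, p


def run_contrasts(
    real_scores: Sequence[SyncScore], surrogate_scores: Sequence[SyncScore]
) -> dict[str, dict[str, float]]:
    """Three signed-rank contrasts on %REC.

    ``task_real_vs_surrogate``, ``task_vs_baseline`` (real groups) and
    ``baseline_real_vs_surrogate``; pairing is by enumeration order
    within each table.  ``direction`` is the sign of the mean paired
    difference (first minus second member of the contrast).
    """

    def rec(scores: Sequence[SyncScore], phase: str) -> list[float]:
        return [s.measures.rec_pct for s in scores if s.phase == phase]

    contrasts = {
        "task_real_vs_surrogate": (rec(real_scores, "task"), rec(surrogate_scores, "task")),
        "task_vs_baseline": (rec(real_scores, "task"), rec(real_scores, "baseline")),
        "baseline_real_vs_surrogate": (
            rec(real_scores, "baseline"),
            rec(surrogate_scores, "baseline"),
        ),
    }
    report = {}
    for name, (a, b) in contrasts.items():
        if len(a) != len(b):
            raise ValueError(f"contrast {name}: unequal table sizes {len(a)} vs {len(b)}")
        pairs = list(zip(a, b))
        t_stat, p = wilcoxon_signed_rank(pairs)
        diff = float(np.mean(np.asarray(a) - np.asarray(b)))
        report[name] = {
            "T": t_stat,
            "p": p,
            "direction": float(np.sign(diff)),
            "mean_diff": diff,
            "n_pairs": len(pairs),
        }
    return report
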