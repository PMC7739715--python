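"""Group x time intervention statistics.

The cohort design is two groups (pre-/post-menopausal) measured at baseline
and after the intervention.  Outcomes measured per participant at both
times are analyzed with a linear mixed model — fixed effects for group,
time and their interaction, a random intercept per participant (compound
symmetry), REML estimation, and t/F tests on containment (residual)
degrees of freedom.  Depot masses are additionally analyzed by a two-way
ANCOVA with the number of analyzed slices as covariate.  Interaction
effects are followed up by ls-means within-group change contrasts
(unadjusted for multiplicity, noted in the report metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .phantoms.cohort import CohortSpec, simulate_cohort

GROUP_LEVELS = ("pre", "post")
TIME_LEVELS = ("baseline", "3 months")


@dataclass
class TermResult:
    estimate: float
    se: float
    statistic: float
    p_value: float
    df: float

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
        }


@dataclass
class EffectReport:
    model: str  # "mixed" | "ancova" | "paired-fallback"
    outcome: str
    terms: dict[str, TermResult]
    lsmeans: dict[str, TermResult] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "outcome": self.outcome,
            "terms": {k: v.to_dict() for k, v in self.terms.items()},
            "lsmeans": {k: v.to_dict() for k, v in self.lsmeans.items()},
            "metadata": self.metadata,
        }


def _validate_table(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    required = {"participant_id", "group", "time", "outcome", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table misses columns {sorted(missing)}")
    df = table[table["outcome"] == outcome].copy()
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    per_group = df.groupby("participant_id")["group"].nunique()
    if (per_group > 1).any():
        raise ValueError("a participant appears in more than one group")
    dup = df.duplicated(subset=["participant_id", "time"])
    if dup.any():
        raise ValueError("more than one value per participant x time x outcome")
    counts = df.groupby("group")["participant_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 participants per group")
    return df


def _t_term(est: float, se: float, df: float) -> TermResult:
    if se == 0 or not np.isfinite(se):
        return TermResult(float(est), float(se), np.nan, np.nan, df)
    t = est / se
    p = 2 * sps.t.sf(abs(t), df)
    return TermResult(float(est), float(se), float(t), float(p), float(df))


def _paired_fallback(df: pd.DataFrame, outcome: str, log_scale: bool) -> EffectReport:
    """Degenerate-variance fallback: per-group paired analyses on subject changes."""
    wide = df.pivot_table(index=["participant_id", "group"], columns="time", values="value").reset_index()
    d = wide[TIME_LEVELS[1]] - wide[TIME_LEVELS[0]]
    terms: dict[str, TermResult] = {}
    lsmeans: dict[str, TermResult] = {}
    changes = {}
    for g in GROUP_LEVELS:
        dg = d[wide["group"] == g].to_numpy(dtype=float)
        n = len(dg)
        se = dg.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        changes[g] = (float(dg.mean()), float(se), n)
        lsmeans[g] = _t_term(dg.mean(), se, n - 1)
    est_time = np.mean([changes[g][0] for g in GROUP_LEVELS])
    se_time = float(np.sqrt(sum(changes[g][1] ** 2 for g in GROUP_LEVELS)) / 2)
    df_time = sum(changes[g][2] for g in GROUP_LEVELS) - 2
    terms["time"] = _t_term(est_time, se_time, df_time)
    est_int = changes[GROUP_LEVELS[1]][0] - changes[GROUP_LEVELS[0]][0]
    se_int = float(np.hypot(changes[GROUP_LEVELS[0]][1], changes[GROUP_LEVELS[1]][1]))
    terms["interaction"] = _t_term(est_int, se_int, df_time)
    base = wide[TIME_LEVELS[0]]
    g0 = base[wide["group"] == GROUP_LEVELS[0]].to_numpy(dtype=float)
    g1 = base[wide["group"] == GROUP_LEVELS[1]].to_numpy(dtype=float)
    tt = sps.ttest_ind(g1, g0, equal_var=True)
    pooled_se = np.sqrt(g0.var(ddof=1) / len(g0) + g1.var(ddof=1) / len(g1))
    terms["group"] = TermResult(
        float(g1.mean() - g0.mean()), float(pooled_se), float(tt.statistic),
        float(tt.pvalue), float(len(g0) + len(g1) - 2),
    )
    return EffectReport(
        model="paired-fallback",
        outcome=outcome,
        terms=terms,
        lsmeans=lsmeans,
        metadata={"log_scale": log_scale, "note": "zero within-subject variance"},
    )


def mixed_model_group_time(
    table: pd.DataFrame,
    outcome: str,
    log_scale: bool = False,
    lsmeans: str = "auto",
    interaction_alpha: float = 0.05,
) -> EffectReport:
    """Mixed model with group, time and group x time, random participant intercept.

    Tests use containment degrees of freedom
    ``n_obs - rank(X) - (n_participants - 1)``.  ``lsmeans`` controls when
    within-group change contrasts are reported: ``"auto"`` (when the
    interaction p <= ``interaction_alpha``), ``"always"`` or ``"never"``.
    A fit with (near-)zero within-subject variance falls back to paired
    per-group analyses with a warning.
    """
    df = _validate_table(table, outcome)
    df = df.copy()
    df["y"] = np.log(df["value"]) if log_scale else df["value"]

    wide = df.pivot_table(index=["participant_id", "group"], columns="time", values="y")
    if wide.shape[1] < 2 or wide.dropna().empty:
        raise ValueError("both time points must be present for at least one participant")
    diffs = wide.dropna()[TIME_LEVELS[1]] - wide.dropna()[TIME_LEVELS[0]]
    centered = diffs - diffs.groupby(wide.dropna().index.get_level_values("group")).transform("mean")
    if float(np.abs(centered).max()) < 1e-12 * max(float(np.abs(df["y"]).max()), 1.0):
        warnings.warn(
            "zero within-subject variance: falling back to paired analysis",
            RuntimeWarning,
        )
        rep = _paired_fallback(df[["participant_id", "group", "time", "value"]].assign(value=df["y"]), outcome, log_scale)
        return rep

    single_group = df["group"].nunique() == 1
    if single_group:
        formula = "y ~ C(time, Treatment('baseline'))"
    else:
        formula = "y ~ C(group, Treatment('pre')) * C(time, Treatment('baseline'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        fit = model.fit(reml=True)

    fe = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(fe), : len(fe)]
    n_obs = len(df)
    n_sub = df["participant_id"].nunique()
    df_resid = n_obs - len(fe) - (n_sub - 1)

    # locate design columns by name (Intercept, group main, time main, interaction)
    names = list(fit.model.exog_names)
    i_time = next(i for i, n in enumerate(names) if "time" in n and ":" not in n)

    def lvec(entries: dict[int, float]) -> np.ndarray:
        v = np.zeros(len(fe))
        for i, val in entries.items():
            v[i] = val
        return v

    if single_group:
        L = {"time": lvec({i_time: 1.0})}
    else:
        i_grp = next(i for i, n in enumerate(names) if "group" in n and ":" not in n)
        i_int = next(i for i, n in enumerate(names) if ":" in n)
        # main effects averaged over the other factor; interaction = difference
        # of within-group changes
        L = {
            "group": lvec({i_grp: 1.0, i_int: 0.5}),
            "time": lvec({i_time: 1.0, i_int: 0.5}),
            "interaction": lvec({i_int: 1.0}),
        }
    terms = {
        name: _t_term(float(l @ fe), float(np.sqrt(l @ cov @ l)), df_resid)
        for name, l in L.items()
    }

    ls: dict[str, TermResult] = {}
    want_ls = lsmeans == "always" or (
        lsmeans == "auto"
        and "interaction" in terms
        and terms["interaction"].p_value <= interaction_alpha
    )
    if want_ls and not single_group:
        contrasts = {
            "pre": lvec({i_time: 1.0}),
            "post": lvec({i_time: 1.0, i_int: 1.0}),
        }
        ls = {
            g: _t_term(float(l @ fe), float(np.sqrt(l @ cov @ l)), df_resid)
            for g, l in contrasts.items()
        }
    return EffectReport(
        model="mixed",
        outcome=outcome,
        terms=terms,
        lsmeans=ls,
        metadata={
            "log_scale": log_scale,
            "df_method": "containment",
            "lsmeans_adjustment": "none",
            "n_participants": int(n_sub),
            "converged": bool(getattr(fit, "converged", True)),
        },
    )


def ancova_group_time(
    table: pd.DataFrame,
    outcome: str,
    covariate: str = "n_slices_analyzed",
    log_scale: bool = False,
) -> EffectReport:
    """Two-way ANCOVA (group, time, interaction) with a continuous covariate.

    Type-III style F tests under sum-to-zero factor coding.  A constant
    covariate is dropped with a warning.
    """
    df = _validate_table(table, outcome)
    df = df.copy()
    df["y"] = np.log(df["value"]) if log_scale else df["value"]
    use_cov = covariate in df.columns and df[covariate].nunique() > 1
    if covariate in df.columns and not use_cov:
        warnings.warn(f"covariate {covariate!r} is constant; dropped", RuntimeWarning)
    if covariate not in df.columns:
        warnings.warn(f"covariate {covariate!r} not present; dropped", RuntimeWarning)
    base = "y ~ C(group, Sum) * C(time, Sum)"
    formula = f"{base} + {covariate}" if use_cov else base
    fit = smf.ols(formula, df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table3 = sm.stats.anova_lm(fit, typ=3)

    name_map = {
        "C(group, Sum)": "group",
        "C(time, Sum)": "time",
        "C(group, Sum):C(time, Sum)": "interaction",
    }
    if use_cov:
        name_map[covariate] = "covariate"
    # coefficient estimates for effect sizes (sum coding: half the difference)
    coefs = fit.params
    ses = fit.bse
    coef_map = {
        "group": next(n for n in coefs.index if n.startswith("C(group, Sum)") and ":" not in n),
        "time": next(n for n in coefs.index if n.startswith("C(time, Sum)") and ":" not in n),
        "interaction": next(n for n in coefs.index if ":" in n),
    }
    terms: dict[str, TermResult] = {}
    for raw, name in name_map.items():
        row = table3.loc[raw]
        if name == "covariate":
            est, se = float(coefs[covariate]), float(ses[covariate])
        else:
            est, se = float(coefs[coef_map[name]]), float(ses[coef_map[name]])
        terms[name] = TermResult(
            estimate=est,
            se=se,
            statistic=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            df=float(fit.df_resid),
        )
    return EffectReport(
        model="ancova",
        outcome=outcome,
        terms=terms,
        metadata={
            "log_scale": log_scale,
            "covariate": covariate if use_cov else None,
            "r_squared": float(fit.rsquared),
        },
    )


def descriptive_mean_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a t-based confidence interval."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    m = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(len(x)))
    q = float(sps.t.ppf(0.5 + confidence / 2.0, len(x) - 1))
    return m, m - q * se, m + q * se


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    alpha: float
    term: str


def power_simulation(
    spec: CohortSpec,
    outcome: str,
    effect: float,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    term: str = "time",
    log_scale: bool = False,
) -> PowerResult:
    """Monte-Carlo rejection rate of one mixed-model term.

    Simulates ``n_reps`` cohorts with the multiplicative ``effect`` applied
    at follow-up to the depot behind ``outcome``, fits the mixed model, and
    counts rejections at ``alpha``.  Returns the power with a 95% binomial
    (normal-approximation) confidence interval.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable estimate")
    depot = outcome[: -len("_mass")] if outcome.endswith("_mass") else outcome
    if depot not in spec.baseline_mean:
        raise ValueError(f"no depot {depot!r} behind outcome {outcome!r}")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        rep_spec = CohortSpec(
            n_per_group=spec.n_per_group,
            baseline_mean={depot: spec.baseline_mean[depot]},
            between_subject_cv=spec.between_subject_cv,
            within_subject_cv=spec.within_subject_cv,
            time_effect={depot: effect},
            group_effect=spec.group_effect,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        table = simulate_cohort(rep_spec, include_uptake=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = mixed_model_group_time(table, outcome, log_scale=log_scale, lsmeans="never")
        p = rep.terms[term].p_value
        if np.isfinite(p) and p < alpha:
            rejections += 1
    power = rejections / n_reps
    half = 1.96 * np.sqrt(max(power * (1 - power), 1e-12) / n_reps)
    return PowerResult(
        power=float(power),
        ci_low=float(max(power - half, 0.0)),
        ci_high=float(min(power + half, 1.0)),
        n_reps=n_reps,
        alpha=alpha,
        term=term,
    )
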