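"""Developmental mixed models: random-intercept LMMs on log10(age).

Measurements (amplitudes, latencies, distinctiveness, noise) from a mixed
cross-sectional/longitudinal cohort are modelled as fixed effects of
log10(age in days) — optionally interacting with category or time window —
with a participant-level random intercept.  Estimation is REML via
statsmodels MixedLM; Wald t-statistics use residual degrees of freedom
(n_obs minus the number of fixed-effect parameters), matching the
t_(df) reporting convention for these designs.  When every participant
contributes a single row the random intercept is unidentified and the model
reduces, by construction, to ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LMMResult:
    fixed_effects: pd.DataFrame   # name, estimate, ci_low, ci_high, t, dof, p
    random_intercept_var: float
    n_obs: int
    n_participants: int
    converged: bool
    formula: str
    method: str                   # "mixedlm" or "ols" (degenerate reduction)

    def effect(self, name: str) -> pd.Series:
        hit = self.fixed_effects[self.fixed_effects["name"].str.contains(
            name, regex=False)]
        if len(hit) == 0:
            raise KeyError(f"no fixed effect matching {name!r}")
        return hit.iloc[0]

    def summary(self) -> str:
        lines = [f"LMM ({self.method}, REML): {self.formula}",
                 f"n_obs={self.n_obs}, n_participants={self.n_participants}, "
                 f"random intercept var={self.random_intercept_var:.4g}, "
                 f"converged={self.converged}"]
        for _, r in self.fixed_effects.iterrows():
            lines.append(
                f"  {r['name']}: beta={r['estimate']:.4g} "
                f"[{r['ci_low']:.4g}, {r['ci_high']:.4g}], "
                f"t({r['dof']:.0f})={r['t']:.3g}, p={r['p']:.3g}")
        return "\n".join(lines)


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if (df["age_days"] <= 0).any():
        raise ValueError("age_days must be positive")
    df["log_age"] = np.log10(df["age_days"].astype(float))
    return df


def _wald_table(names, params, bse, dof) -> pd.DataFrame:
    tvals = np.where(bse > 0, params / np.where(bse > 0, bse, 1.0), 0.0)
    tq = stats.t.ppf(0.975, dof)
    p = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return pd.DataFrame({
        "name": names, "estimate": params,
        "ci_low": params - tq * bse, "ci_high": params + tq * bse,
        "t": tvals, "dof": dof, "p": p,
    })


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: str = "log_age",
    group_col: str = "participant_id",
) -> LMMResult:
    """Random-intercept LMM ``response ~ 1 + fixed + (1 | participant)``.

    ``fixed`` is a patsy formula right-hand side; ``log_age`` (log10 of
    age_days) is available as a predictor.  REML estimation; non-convergence
    is flagged on the result rather than silently replaced.
    """
    df = _prepare(table)
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 participants")
    formula = f"{response} ~ {fixed}"
    single_obs = df.groupby(group_col).size().max() == 1

    if np.allclose(df[response].to_numpy(dtype=float), 0.0):
        # all-zero response: exact degenerate answer
        import patsy
        x = patsy.dmatrix(fixed, df, return_type="dataframe")
        names = list(x.columns)
        k = len(names)
        dof = len(df) - k
        return LMMResult(_wald_table(names, np.zeros(k), np.zeros(k), dof),
                         0.0, len(df), df[group_col].nunique(), True,
                         formula, "degenerate-zero")

    if single_obs:
        import statsmodels.formula.api as smf
        fit = smf.ols(formula, data=df).fit()
        dof = int(fit.df_resid)
        tab = _wald_table(list(fit.params.index), fit.params.to_numpy(),
                          fit.bse.to_numpy(), dof)
        return LMMResult(tab, 0.0, len(df), df[group_col].nunique(), True,
                         formula, "ols")

    import statsmodels.formula.api as smf
    model = smf.mixedlm(formula, data=df, groups=df[group_col])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True))
    fe_names = [n for n in fit.params.index if n != "Group Var"]
    params = fit.params[fe_names].to_numpy()
    bse = fit.bse[fe_names].to_numpy()
    dof = len(df) - len(fe_names)
    tab = _wald_table(fe_names, params, bse, dof)
    re_var = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
    return LMMResult(tab, re_var, len(df), df[group_col].nunique(),
                     converged, formula, "mixedlm")


def posthoc_by_level(
    table: pd.DataFrame,
    response: str,
    level_variable: str,
    fixed: str = "log_age",
    effect: str = "log_age",
    q: float = 0.05,
    group_col: str = "participant_id",
) -> pd.DataFrame:
    """One log-age LMM per level of ``level_variable`` with BH correction of
    the named effect's p-values across levels.  Levels with fewer than 3
    participants are skipped (logged in the output)."""
    from statsmodels.stats.multitest import multipletests

    levels = list(pd.unique(table[level_variable]))
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    rows, results = [], {}
    for lev in levels:
        sub = table[table[level_variable] == lev]
        if sub[group_col].nunique() < 3:
            rows.append({"level": lev, "skipped": True})
            continue
        res = fit_lmm(sub, response, fixed=fixed, group_col=group_col)
        eff = res.effect(effect)
        rows.append({"level": lev, "skipped": False,
                     "estimate": eff["estimate"], "ci_low": eff["ci_low"],
                     "ci_high": eff["ci_high"], "t": eff["t"],
                     "dof": eff["dof"], "p": eff["p"]})
        results[lev] = res
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["p_fdr"] = np.nan
    out["significant"] = False
    if tested.any():
        reject, p_adj, *_ = multipletests(out.loc[tested, "p"], alpha=q,
                                          method="fdr_bh")
        out.loc[tested, "p_fdr"] = p_adj
        out.loc[tested, "significant"] = reject
    out.attrs["results"] = results
    return out


def noise_lmm(table: pd.DataFrame, response: str = "noise_amplitude",
              group_col: str = "participant_id") -> LMMResult:
    """Noise amplitude ~ 1 + log10(age) + (1 | participant)."""
    return fit_lmm(table, response, fixed="log_age", group_col=group_col)
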