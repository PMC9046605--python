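"""Per-outcome mixed-model inference for the pre/post two-arm design.

Each discrete outcome is modelled as

    y_ij = b0 + b_g 1[IG] + b_t 1[week8] + b_gt 1[IG]*1[week8] + u_i + e_ij

with a Gaussian random intercept u_i per participant, fitted by REML
(statsmodels MixedLM). The group-by-time interaction b_gt is the primary
comparison: it equals the difference-in-differences of the four cell means.
Wald inference uses a t reference distribution with n1 + n2 - 2 degrees of
freedom (the exact df for the interaction in the balanced complete-case
design, where it reduces to a two-sample comparison of within-subject change
scores). Estimated marginal means are
the model's four cell means; pairwise comparisons between them are
Bonferroni-adjusted. Cohen's d between groups at the post assessment uses
the n-weighted pooled sd, with bins negligible (<0.2), small (0.2-0.5),
medium (0.5-0.8), large (>=0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, ParameterError, SampleSizeError

CELLS = (("CG", "baseline"), ("CG", "week8"), ("IG", "baseline"), ("IG", "week8"))

#: pairwise EMM comparisons reported (the within-group changes and the
#: between-group contrasts at each time); Bonferroni family size = 4
PAIRWISE = {
    "IG_week8_vs_baseline": (("IG", "week8"), ("IG", "baseline")),
    "CG_week8_vs_baseline": (("CG", "week8"), ("CG", "baseline")),
    "IG_vs_CG_baseline": (("IG", "baseline"), ("CG", "baseline")),
    "IG_vs_CG_week8": (("IG", "week8"), ("CG", "week8")),
}

@dataclass
class MixedModelResult:
    outcome_name: str
    fixed_effects: pd.DataFrame     # index: term; cols: estimate, se, p
    interaction_estimate: float
    interaction_se: float
    interaction_p: float
    interaction_ci: tuple
    emm: dict                       # (group, time) -> (mean, lo, hi)
    pairwise_p_bonferroni: dict
    cohens_d: float | None = None
    d_label: str | None = None
    method: str = "mixed"           # "mixed" or "ols_fallback"


def bonferroni_adjust(p_values, family_size: int):
    """min(1, p * k) element-wise."""
    if family_size < 1:
        raise ParameterError("family_size must be >= 1")
    p = np.asarray(p_values, float)
    return np.minimum(p * family_size, 1.0)


def cohens_d(post_means, post_sds, n_per_group):
    """Between-group Cohen's d from summary statistics, with its size label.

    d = |m1 - m2| / s_pooled where s_pooled is the n-weighted pooled sd.
    """
    (m1, m2), (s1, s2), (n1, n2) = post_means, post_sds, n_per_group
    if s1 <= 0 or s2 <= 0:
        raise ParameterError("post_sds must be positive")
    pooled = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ParameterError("pooled sd is zero; d undefined")
    d = abs(m1 - m2) / pooled
    if d < 0.2:
        label = "negligible"
    elif d < 0.5:
        label = "small"
    elif d < 0.8:
        label = "medium"
    else:
        label = "large"
    return float(d), label


def _design(df: pd.DataFrame) -> np.ndarray:
    g = (df["group"] == "IG").to_numpy(float)
    t = (df["time"] == "week8").to_numpy(float)
    return np.column_stack([np.ones(len(df)), g, t, g * t])


_TERMS = ("intercept", "group[IG]", "time[week8]", "group[IG]:time[week8]")


def fit_interaction_model(outcomes_table: pd.DataFrame, outcome_name: str,
                          reml: bool = True) -> MixedModelResult:
    """Fit the group x time mixed model for one outcome.

    ``outcomes_table`` is tidy: subject_id, group, time, outcome, value.
    Missing values (e.g. absent impact transient) are dropped listwise for
    that outcome. Falls back to OLS when the mixed fit is singular or fails
    to converge (``method`` records which path was used).
    """
    df = outcomes_table[outcomes_table["outcome"] == outcome_name].copy()
    df = df.dropna(subset=["value"])
    if df.empty:
        raise DataError(f"no data for outcome '{outcome_name}'")
    for grp in ("IG", "CG"):
        if df.loc[df.group == grp, "subject_id"].nunique() < 2:
            raise SampleSizeError(f"need >= 2 subjects in group {grp}")
    if df["time"].nunique() < 2:
        raise SampleSizeError("both assessment times must be present")

    X = _design(df)
    y = df["value"].to_numpy(float)
    groups = df["subject_id"].to_numpy()

    method = "mixed"
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(y, X, groups=groups)
        for opt_method in (None, "powell"):
            try:
                res = (md.fit(reml=reml) if opt_method is None
                       else md.fit(reml=reml, method=opt_method))
            except (np.linalg.LinAlgError, ValueError):
                res = None
                continue
            if np.all(np.isfinite(res.bse_fe)) and np.all(res.bse_fe > 0):
                break
            res = None
    if res is None:
        method = "ols_fallback"
        res = sm.OLS(y, X).fit()
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        cov = np.asarray(res.cov_params())
    else:
        params = np.asarray(res.fe_params)
        bse = np.asarray(res.bse_fe)
        cov = np.asarray(res.cov_params())[:4, :4]

    from scipy.stats import t as t_dist
    df_wald = df.loc[df.group == "IG", "subject_id"].nunique() \
        + df.loc[df.group == "CG", "subject_id"].nunique() - 2
    qt = float(t_dist.ppf(0.975, df_wald))
    pvals = 2.0 * t_dist.sf(np.abs(params) / bse, df_wald)
    fixed = pd.DataFrame({"estimate": params, "se": bse, "p": pvals},
                         index=list(_TERMS))
    b_int, se_int, p_int = params[3], bse[3], float(pvals[3])
    ci = (b_int - qt * se_int, b_int + qt * se_int)

    cell_rows = {("CG", "baseline"): np.array([1.0, 0, 0, 0]),
                 ("CG", "week8"): np.array([1.0, 0, 1, 0]),
                 ("IG", "baseline"): np.array([1.0, 1, 0, 0]),
                 ("IG", "week8"): np.array([1.0, 1, 1, 1])}
    emm = {}
    for cell, xr in cell_rows.items():
        mu = float(xr @ params)
        se = float(np.sqrt(xr @ cov @ xr))
        emm[cell] = (mu, mu - qt * se, mu + qt * se)

    raw = {}
    for name, (ca, cb) in PAIRWISE.items():
        c = cell_rows[ca] - cell_rows[cb]
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        raw[name] = float(2.0 * t_dist.sf(abs(est) / se, df_wald)) if se > 0 else 1.0
    adj = bonferroni_adjust(list(raw.values()), len(PAIRWISE))
    pairwise = dict(zip(raw.keys(), (float(p) for p in adj)))

    return MixedModelResult(
        outcome_name=outcome_name, fixed_effects=fixed,
        interaction_estimate=float(b_int), interaction_se=float(se_int),
        interaction_p=p_int, interaction_ci=(float(ci[0]), float(ci[1])),
        emm=emm, pairwise_p_bonferroni=pairwise, method=method)


def summarize_outcomes(outcomes_table: pd.DataFrame,
                       reml: bool = True) -> pd.DataFrame:
    """Per-outcome results table: cell mean (sd) per arm, interaction p, d.

    Cohen's d compares the groups at the post assessment from the raw
    summaries (the convention that reproduces the checkable published value).
    """
    rows = []
    for name in outcomes_table["outcome"].unique():
        sub = outcomes_table[outcomes_table["outcome"] == name].dropna(subset=["value"])
        cells = {}
        for (grp, tim), g in sub.groupby(["group", "time"]):
            cells[(grp, tim)] = (g["value"].mean(), g["value"].std(ddof=1), len(g))
        fit = fit_interaction_model(outcomes_table, name, reml=reml)
        d = d_label = None
        if ("IG", "week8") in cells and ("CG", "week8") in cells:
            (m1, s1, n1), (m2, s2, n2) = cells[("IG", "week8")], cells[("CG", "week8")]
            if s1 > 0 and s2 > 0:
                d, d_label = cohens_d((m1, m2), (s1, s2), (n1, n2))
        rows.append({
            "outcome": name,
            "ig_pre_mean": cells.get(("IG", "baseline"), (np.nan,) * 3)[0],
            "ig_pre_sd": cells.get(("IG", "baseline"), (np.nan,) * 3)[1],
            "ig_post_mean": cells.get(("IG", "week8"), (np.nan,) * 3)[0],
            "ig_post_sd": cells.get(("IG", "week8"), (np.nan,) * 3)[1],
            "cg_pre_mean": cells.get(("CG", "baseline"), (np.nan,) * 3)[0],
            "cg_pre_sd": cells.get(("CG", "baseline"), (np.nan,) * 3)[1],
            "cg_post_mean": cells.get(("CG", "week8"), (np.nan,) * 3)[0],
            "cg_post_sd": cells.get(("CG", "week8"), (np.nan,) * 3)[1],
            "interaction_estimate": fit.interaction_estimate,
            "interaction_p": fit.interaction_p,
            "cohens_d": d, "d_label": d_label, "fit_method": fit.method,
        })
    return pd.DataFrame(rows)
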