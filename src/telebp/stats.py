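"""The statistical decision tree applied to grouped hemodynamic summaries.

Routing: every comparison group is tested for normality (Shapiro-Wilk) and the
groups jointly for variance homogeneity (Bartlett). Only when all pass at
alpha does the parametric branch run — 2- or 3-factor ANOVA (with repeated
measures where appropriate) followed by Tukey's HSD (2-factor families) or
Bonferroni-corrected unpaired t tests (3-factor families). Otherwise the
nonparametric branch runs: Kruskal-Wallis followed by the Steel-Dwass
(Steel-Dwass-Critchlow-Fligner) all-pairs multiple comparison.

Repeated measures are handled with classical within-subject error strata on
balanced designs (no mixed-model REML): each within-subject effect is tested
against its subject-interaction stratum, with the Greenhouse-Geisser epsilon
reported and applied alongside the uncorrected p.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# result containers
# ----------------------------------------------------------------------


@dataclass
class DecisionTrace:
    """Outcome of the normality / variance-homogeneity gate."""

    shapiro_p: dict
    bartlett_p: float
    route: str  # 'parametric' | 'nonparametric'
    reason: str

    def __str__(self) -> str:  # human-readable log form
        lines = [f"route: {self.route} ({self.reason})"]
        for g, p in self.shapiro_p.items():
            lines.append(f"  shapiro {g}: p={p:.4g}" if np.isfinite(p) else f"  shapiro {g}: n/a")
        lines.append(f"  bartlett: p={self.bartlett_p:.4g}" if np.isfinite(self.bartlett_p) else "  bartlett: n/a")
        return "\n".join(lines)


@dataclass
class TestResult:
    """A named test with its statistic, p-value and optional tables."""

    name: str
    statistic: float
    p_value: float
    df: tuple = ()
    table: pd.DataFrame | None = None  # per-effect ANOVA table
    pairwise: pd.DataFrame | None = None  # comparison, estimate, p_adj
    extra: dict = field(default_factory=dict)


def _groups(table: pd.DataFrame, group_cols, dv: str):
    gb = table.groupby(list(group_cols), observed=True, sort=True)[dv]
    return {key if isinstance(key, tuple) else (key,): g.to_numpy(dtype=float) for key, g in gb}


# ----------------------------------------------------------------------
# routing
# ----------------------------------------------------------------------


def route(
    table: pd.DataFrame,
    group_cols,
    dv: str = "value",
    alpha: float = 0.05,
) -> DecisionTrace:
    """Decide parametric vs nonparametric for the groups defined by ``group_cols``."""
    groups = _groups(table, group_cols, dv)
    shapiro_p: dict = {}
    reasons = []
    nonparam = False
    for key, vals in groups.items():
        label = "/".join(str(k) for k in key)
        if vals.size < 3:
            shapiro_p[label] = float("nan")
            nonparam = True
            reasons.append(f"group {label} too small for Shapiro-Wilk (n={vals.size})")
            continue
        if np.ptp(vals) == 0:
            shapiro_p[label] = float("nan")
            nonparam = True
            reasons.append(f"group {label} has zero variance")
            continue
        p = float(sps.shapiro(vals).pvalue)
        shapiro_p[label] = p
        if p < alpha:
            nonparam = True
            reasons.append(f"normality rejected for {label} (p={p:.3g})")
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            bart_p = float(sps.bartlett(*groups.values()).pvalue)
    except ValueError:
        bart_p = float("nan")
    if np.isnan(bart_p):
        nonparam = True
        reasons.append("Bartlett undefined (degenerate groups)")
    elif bart_p < alpha:
        nonparam = True
        reasons.append(f"variance homogeneity rejected (p={bart_p:.3g})")
    if nonparam:
        return DecisionTrace(shapiro_p, bart_p, "nonparametric", "; ".join(reasons))
    return DecisionTrace(
        shapiro_p, bart_p, "parametric", "all groups normal with similar variances"
    )


# ----------------------------------------------------------------------
# factorial / repeated-measures ANOVA
# ----------------------------------------------------------------------


def factorial_anova(
    table: pd.DataFrame,
    factors,
    repeated_on=None,
    dv: str = "value",
    subject: str = "animal",
    posthoc: str | None = "auto",
    alpha: float = 0.05,
) -> TestResult:
    """Main and interaction F tests for a 1-3 factor design.

    ``repeated_on`` lists within-subject factors (each subject observed at
    every level). Between-subject designs use an OLS type-II decomposition;
    designs with within factors use classical balanced split-plot strata
    (at most one between and two within factors).

    Post hoc: Tukey HSD over all cells when the design has at most two
    factors, Bonferroni-corrected unpaired t tests for three-factor designs
    (``posthoc='auto'``); ``None`` skips it.
    """
    factors = list(factors)
    repeated_on = list(repeated_on or [])
    if not factors or len(factors) > 3:
        raise ConfigError("factorial_anova supports 1-3 factors")
    for f in factors:
        if table[f].nunique() < 2:
            raise DataError(f"factor {f} needs >= 2 levels")
    if any(f not in factors for f in repeated_on):
        raise ConfigError("repeated_on must be a subset of factors")

    if repeated_on:
        eff = _split_plot_anova(table, factors, repeated_on, dv, subject)
    else:
        eff = _between_anova(table, factors, dv)

    pair = None
    if posthoc == "auto":
        if len(factors) <= 2:
            pair = tukey_posthoc(table, factors, dv)
        else:
            pair = bonferroni_t_posthoc(table, factors, dv)
    first = eff.iloc[0]
    return TestResult(
        name="factorial ANOVA" + (" (repeated measures)" if repeated_on else ""),
        statistic=float(first["F"]),
        p_value=float(first["p"]),
        df=(float(first["df1"]), float(first["df2"])),
        table=eff,
        pairwise=pair,
    )


def _between_anova(table, factors, dv):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table.rename(columns={dv: "_dv"})
    formula = "_dv ~ " + " * ".join(f"C(Q('{f}'))" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    rows = []
    resid_df = float(aov.loc["Residual", "df"])
    for name, row in aov.iterrows():
        if name == "Residual":
            continue
        clean = name
        for f in factors:
            clean = clean.replace(f"C(Q('{f}'))", f)
        rows.append(
            {
                "effect": clean.replace(":", " x "),
                "ss": float(row["sum_sq"]),
                "df1": float(row["df"]),
                "df2": resid_df,
                "F": float(row["F"]),
                "p": float(row["PR(>F)"]),
                "gg_eps": np.nan,
                "p_gg": np.nan,
            }
        )
    return pd.DataFrame(rows)


def _check_balanced(table, cols, subject=None):
    counts = table.groupby(cols, observed=True).size()
    if counts.nunique() != 1:
        raise DataError("repeated-measures ANOVA requires a balanced design")
    return int(counts.iloc[0])


def _split_plot_anova(table, factors, within, dv, subject):
    """Balanced split-plot ANOVA: <=1 between factor, 1-2 within factors."""
    between = [f for f in factors if f not in within]
    if len(between) > 1:
        raise ConfigError("at most one between-subject factor is supported")
    if len(within) > 2:
        raise ConfigError("at most two within-subject factors are supported")
    if subject not in table.columns:
        raise DataError(f"subject column {subject!r} missing")

    d = table.copy()
    if not between:
        d["_b"] = "all"
        between = ["_b"]
    b, = between
    w = list(within)
    reps = _check_balanced(d, [subject] + w)
    if reps != 1:
        # average replicate measurements within subject x condition
        d = d.groupby([b, subject] + w, observed=True, as_index=False)[dv].mean()

    y = d[dv].to_numpy(dtype=float)
    N = y.size
    grand = y.mean()

    levels = {f: d[f].nunique() for f in [b] + w}
    n_subj = d[subject].nunique()
    s_per_group = n_subj // levels[b]
    if s_per_group * levels[b] != n_subj:
        raise DataError("subjects are not balanced across between-factor levels")

    def U(cols):
        if not cols:
            return N * grand**2
        m = d.groupby(list(cols), observed=True)[dv].mean()
        r = N / m.size
        return float(r * (m.to_numpy() ** 2).sum())

    fixed = [b] + w
    ss = {}
    # fixed-effect SS by inclusion-exclusion over subsets
    for k in range(1, len(fixed) + 1):
        for combo in itertools.combinations(fixed, k):
            total = 0.0
            for j in range(0, k + 1):
                for sub in itertools.combinations(combo, j):
                    total += (-1) ** (k - j) * U(sub)
            ss[combo] = total

    u_s = U([subject])
    ss_subj = u_s - U([b])
    strata = {(): (ss_subj, levels[b] * (s_per_group - 1))}
    for wi in w:
        val = U([subject, wi]) - u_s - U([b, wi]) + U([b])
        dfv = levels[b] * (s_per_group - 1) * (levels[wi] - 1)
        strata[(wi,)] = (val, dfv)
    ss_total = float(((y - grand) ** 2).sum())
    if len(w) == 2:
        used = sum(v for v in ss.values()) + ss_subj + strata[(w[0],)][0] + strata[(w[1],)][0]
        resid = ss_total - used
        df_res = (
            levels[b]
            * (s_per_group - 1)
            * (levels[w[0]] - 1)
            * (levels[w[1]] - 1)
        )
        strata[tuple(w)] = (max(resid, 0.0), df_res)

    def stratum_for(combo):
        wpart = tuple(f for f in combo if f in w)
        return wpart

    def df_effect(combo):
        out = 1
        for f in combo:
            out *= levels[f] - 1
        return out

    rows = []
    order = sorted(ss, key=lambda c: (len(c), fixed.index(c[0])))
    gg_cache = {}
    for combo in order:
        if b in combo and d[b].nunique() == 1:
            continue  # synthetic all-subjects group and its interactions
        wpart = stratum_for(combo)
        err_ss, err_df = strata[wpart]
        df1 = df_effect(combo)
        if err_df <= 0 or err_ss <= 0:
            raise DataError("singular design: empty error stratum")
        F = (ss[combo] / df1) / (err_ss / err_df)
        p = float(sps.f.sf(F, df1, err_df))
        eps = np.nan
        p_gg = np.nan
        if wpart:  # within-subject effect: Greenhouse-Geisser correction
            if wpart not in gg_cache:
                gg_cache[wpart] = _gg_epsilon(d, dv, subject, b, list(wpart))
            eps = gg_cache[wpart]
            if np.isfinite(eps):
                p_gg = float(sps.f.sf(F, df1 * eps, err_df * eps))
        rows.append(
            {
                "effect": " x ".join(combo),
                "ss": ss[combo],
                "df1": float(df1),
                "df2": float(err_df),
                "F": float(F),
                "p": p,
                "gg_eps": eps,
                "p_gg": p_gg,
            }
        )
    return pd.DataFrame(rows)


def _gg_epsilon(d, dv, subject, between, wcols):
    """Greenhouse-Geisser epsilon for the within-effect defined by ``wcols``."""
    wide = d.pivot_table(
        index=[between, subject], columns=wcols, values=dv, observed=True
    )
    k = wide.shape[1]
    if k < 2 or wide.shape[0] <= k:
        return np.nan
    # pool covariance within between-groups
    centered = wide - wide.groupby(level=0, observed=True).transform("mean")
    X = centered.to_numpy()
    S = X.T @ X / max(X.shape[0] - d[between].nunique(), 1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    if den <= 0:
        return np.nan
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


# ----------------------------------------------------------------------
# post hoc families
# ----------------------------------------------------------------------


def _cells(table, factors, dv):
    lab = table[factors].astype(str).agg("/".join, axis=1)
    return lab, table[dv].to_numpy(dtype=float)


def tukey_posthoc(table, factors, dv: str = "value", alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over all cells of the crossed ``factors``."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    lab, y = _cells(table, factors, dv)
    res = pairwise_tukeyhsd(y, lab.to_numpy(), alpha=alpha)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "comparison": [f"{a} vs {b}" for a, b in pairs],
            "estimate": res.meandiffs,
            "p_adj": res.pvalues,
        }
    )


def bonferroni_t_posthoc(table, factors, dv: str = "value") -> pd.DataFrame:
    """All-pairs unpaired t tests with Bonferroni adjustment (p_adj = min(1, m*p))."""
    lab, y = _cells(table, factors, dv)
    keys = sorted(lab.unique())
    pairs = list(itertools.combinations(keys, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = y[lab == a], y[lab == b]
        t, p = sps.ttest_ind(xa, xb)
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "estimate": float(xa.mean() - xb.mean()),
                "p_adj": float(min(1.0, m * p)),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# nonparametric branch
# ----------------------------------------------------------------------


def kruskal_wallis(table: pd.DataFrame, group_cols, dv: str = "value") -> TestResult:
    """Kruskal-Wallis rank test with tie correction."""
    groups = _groups(table, group_cols, dv)
    if len(groups) < 2:
        raise DataError("need >= 2 groups")
    vals = list(groups.values())
    allv = np.concatenate(vals)
    if np.ptp(allv) == 0:
        warnings.warn("all values tied; Kruskal-Wallis H set to 0, p to 1")
        return TestResult("Kruskal-Wallis", statistic=0.0, p_value=1.0, df=(len(groups) - 1,))
    H, p = sps.kruskal(*vals)
    return TestResult("Kruskal-Wallis", statistic=float(H), p_value=float(p), df=(len(groups) - 1,))


def steel_dwass(table: pd.DataFrame, group_cols, dv: str = "value") -> TestResult:
    """Steel-Dwass(-Critchlow-Fligner) all-pairs nonparametric comparison.

    For each pair of groups the two-sample Wilcoxon rank-sum statistic is
    computed on the pair's own (tie-corrected) ranks, standardised, and
    referred to the studentized-range distribution with k = number of groups
    (df = infinity), giving family-adjusted p-values.
    """
    groups = _groups(table, group_cols, dv)
    k = len(groups)
    if k < 3:
        raise DataError("Steel-Dwass needs >= 3 groups")
    for key, v in groups.items():
        if v.size < 2:
            raise DataError(f"group {key} has n < 2")
    keys = list(groups)
    rows = []
    for (ka, kb) in itertools.combinations(keys, 2):
        a, b = groups[ka], groups[kb]
        na, nb = a.size, b.size
        N = na + nb
        ranks = sps.rankdata(np.concatenate([a, b]))
        ra = float(ranks[:na].sum())
        E = na * (N + 1) / 2.0
        V = na * nb / (N * (N - 1)) * (float((ranks**2).sum()) - N * (N + 1) ** 2 / 4.0)
        la = "/".join(str(x) for x in ka)
        lb = "/".join(str(x) for x in kb)
        if V <= 0:
            rows.append({"comparison": f"{la} vs {lb}", "estimate": 0.0, "statistic": 0.0, "p_adj": 1.0})
            continue
        t = (ra - E) / np.sqrt(V)
        p_adj = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, np.inf))
        rows.append(
            {
                "comparison": f"{la} vs {lb}",
                "estimate": float(np.median(a) - np.median(b)),
                "statistic": float(t),
                "p_adj": min(1.0, p_adj),
            }
        )
    pair = pd.DataFrame(rows)
    best = pair.loc[pair["p_adj"].idxmin()]
    return TestResult(
        "Steel-Dwass",
        statistic=float(best["statistic"]),
        p_value=float(best["p_adj"]),
        pairwise=pair,
    )


# ----------------------------------------------------------------------
# paired comparison (dipper logic support)
# ----------------------------------------------------------------------


def paired_compare(x, y, alpha: float = 0.05) -> TestResult:
    """Paired comparison of two matched samples.

    Differences ``y - x`` are tested for normality (Shapiro-Wilk at ``alpha``);
    a paired t test is used when normality holds, a Wilcoxon signed-rank test
    otherwise. Constant nonzero differences fall back to the exact signed-rank
    test (the smallest attainable p for that n); identical vectors give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DataError("need paired vectors of equal length >= 3")
    d = y - x
    effect = float(d.mean())
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult("paired (degenerate)", statistic=0.0, p_value=1.0,
                              extra={"effect": 0.0, "normal": True})
        p = float(min(1.0, 2.0 * 0.5 ** d.size))  # exact sign-test bound
        return TestResult("Wilcoxon signed-rank (exact, constant shift)",
                          statistic=float(d.size * (d.size + 1) / 2), p_value=p,
                          extra={"effect": effect, "normal": False})
    sw_p = float(sps.shapiro(d).pvalue)
    if sw_p >= alpha:
        t, p = sps.ttest_rel(y, x)
        return TestResult("paired t", statistic=float(t), p_value=float(p),
                          df=(x.size - 1,), extra={"effect": effect, "normal": True,
                                                   "shapiro_p": sw_p})
    stat, p = sps.wilcoxon(y, x)
    return TestResult("Wilcoxon signed-rank", statistic=float(stat), p_value=float(p),
                      extra={"effect": effect, "normal": False, "shapiro_p": sw_p})
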