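"""The study's statistical battery, with structured result objects.

Covers the model families used to contrast day- and night-shift groups:

* pooled-variance two-sample t-tests (demographics, baseline scores);
* Fisher's exact test on 2×2 tables with the sample (cross-product) odds
  ratio;
* three-way main-effects ANOVA (shift + age group + gender) with Type II
  sums of squares and model-based estimated marginal means;
* 2 (shift) × 6 (time-of-day bin) repeated-measures ANOVA with Mauchly's
  sphericity test, Greenhouse–Geisser correction, and uncorrected (Fisher
  LSD) per-bin pairwise comparisons;
* linear mixed models with participant random intercepts for momentary
  (EMA) outcomes, fixed effects shift × work status;
* standardized-β linear regressions relating an activity or sleep feature
  to a baseline behavioural score, with a shift × feature interaction.

statsmodels does the model fitting; pingouin handles the repeated-measures
machinery.  Result objects keep full precision — rounding happens only in
report tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "FisherResult",
    "AnovaResult",
    "RmAnovaResult",
    "MixedModelResult",
    "RegressionResult",
    "two_sample_ttest",
    "fisher_exact_2x2",
    "three_way_anova",
    "rm_anova_2x6",
    "lmm_ema",
    "std_regression",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


@dataclass
class FisherResult:
    table: np.ndarray
    odds_ratio: float
    p: float
    infinite: bool = False


@dataclass
class AnovaResult:
    #: term -> (F, df_num, df_den, p)
    terms: dict[str, tuple[float, float, float, float]]
    #: factor -> level -> (emm, se, ci_lo, ci_hi)
    emmeans: dict[str, dict[str, tuple[float, float, float, float]]]
    df_resid: float
    nobs: int


@dataclass
class RmAnovaResult:
    #: term -> (F, df1, df2, p_uncorrected)
    terms: dict[str, tuple[float, float, float, float]]
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    #: within term -> (df1_corrected, df2_corrected, p_corrected); present when
    #: sphericity was rejected at 0.05
    corrected: dict[str, tuple[float, float, float]]
    sphericity_met: bool
    #: bin label -> TTestResult (Fisher-LSD pairwise, uncorrected)
    pairwise: dict[str, TTestResult]
    n_per_group: dict[str, int]


@dataclass
class MixedModelResult:
    #: term -> (estimate, se, t, df, p)
    fixed: dict[str, tuple[float, float, float, float, float]]
    random_intercept_var: float
    resid_var: float
    n_obs: int
    n_participants: int
    n_excluded: int
    converged: bool
    singular: bool = False


@dataclass
class RegressionResult:
    #: term -> (std_beta, t, p)
    terms: dict[str, tuple[float, float, float]]
    adj_r2: float
    r2: float
    f: float
    df_model: float
    df_resid: float
    n: int


def two_sample_ttest(x, y) -> TTestResult:
    """Independent two-sample t-test with pooled variance (df = n1+n2−2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        raise ValueError("undefined statistic: zero variance in both groups, equal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(
        t=float(t),
        df=len(x) + len(y) - 2,
        p=float(p),
        mean1=float(x.mean()),
        sd1=float(np.std(x, ddof=1)),
        n1=len(x),
        mean2=float(y.mean()),
        sd2=float(np.std(y, ddof=1)),
        n2=len(y),
    )


def fisher_exact_2x2(table) -> FisherResult:
    """Fisher's exact test with the sample odds ratio (a·d)/(b·c).

    Rows are groups, columns trait present/absent.  The two-sided p sums
    hypergeometric probabilities no larger than the observed table's.  A
    zero off-diagonal cell makes the odds ratio infinite; it is reported as
    ``inf`` with the ``infinite`` flag set.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table must be 2x2 non-negative integer counts")
        t = t.astype(int)
    (a, b), (c, d) = t
    _, p = sps.fisher_exact(t, alternative="two-sided")
    if b == 0 or c == 0:
        return FisherResult(table=t, odds_ratio=float("inf"), p=float(p), infinite=True)
    return FisherResult(table=t, odds_ratio=(a * d) / (b * c), p=float(p))


_FACTOR_LEVELS = {
    "shift": ("day", "night"),
    "age_group": ("<40", ">=40"),
    "gender": ("female", "male"),
}


def three_way_anova(data: pd.DataFrame, outcome: str) -> AnovaResult:
    """Main-effects ANOVA of ``outcome`` on shift, age group, and gender.

    Type II sums of squares on the (generally unbalanced) design, no
    interactions.  Estimated marginal means average model predictions
    equally over the full factor grid, with model-based SEs and 95%
    t-intervals.

    ``data`` needs columns ``outcome``, ``shift`` (day/night), ``age_group``
    (<40 / >=40), ``gender`` (female/male).
    """
    df = data.dropna(subset=[outcome, "shift", "age_group", "gender"]).copy()
    for factor, levels in _FACTOR_LEVELS.items():
        present = set(df[factor].unique())
        if not present <= set(levels):
            raise ValueError(f"unexpected {factor} levels: {present - set(levels)}")
        if len(present) < 2:
            raise ValueError(f"factor {factor!r} has an empty level")
    if np.var(df[outcome].to_numpy(dtype=float)) == 0:
        raise ValueError("outcome is constant: ANOVA undefined (zero residual variance)")

    df = df.rename(columns={outcome: "_y"})
    model = smf.ols("_y ~ C(shift) + C(age_group) + C(gender)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    terms = {}
    name_map = {"C(shift)": "shift", "C(age_group)": "age_group", "C(gender)": "gender"}
    for raw, term in name_map.items():
        row = aov.loc[raw]
        terms[term] = (
            float(row["F"]),
            float(row["df"]),
            float(aov.loc["Residual", "df"]),
            float(row["PR(>F)"]),
        )

    # EMMs: average the design rows of the full factor grid
    grid = pd.MultiIndex.from_product(
        [_FACTOR_LEVELS["shift"], _FACTOR_LEVELS["age_group"], _FACTOR_LEVELS["gender"]],
        names=["shift", "age_group", "gender"],
    ).to_frame(index=False)
    design = model.model.data.design_info
    from patsy import dmatrix

    X = np.asarray(dmatrix(design, grid))
    cov = model.cov_params().to_numpy()
    beta = model.params.to_numpy()
    df_resid = float(model.df_resid)
    tcrit = sps.t.ppf(0.975, df_resid)
    emmeans: dict[str, dict[str, tuple[float, float, float, float]]] = {}
    for factor, levels in _FACTOR_LEVELS.items():
        emmeans[factor] = {}
        for level in levels:
            mask = (grid[factor] == level).to_numpy()
            L = X[mask].mean(axis=0)
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            emmeans[factor][level] = (est, se, est - tcrit * se, est + tcrit * se)
    return AnovaResult(terms=terms, emmeans=emmeans, df_resid=df_resid, nobs=int(model.nobs))


def rm_anova_2x6(
    data: pd.DataFrame,
    value_col: str = "value",
    bin_col: str = "bin",
    subject_col: str = "participant_id",
    shift_col: str = "shift",
    alpha_sphericity: float = 0.05,
) -> RmAnovaResult:
    """2 (shift, between) × 6 (diurnal bin, within) repeated-measures ANOVA.

    Subjects missing any bin are dropped (listwise).  Mauchly's test probes
    sphericity of the within factor; when rejected at ``alpha_sphericity``
    the Greenhouse–Geisser-corrected dfs and p-values are reported for the
    within and interaction terms.  Per-bin day-vs-night contrasts are
    uncorrected pooled-variance t-tests (Fisher's LSD convention).
    """
    df = data[[subject_col, shift_col, bin_col, value_col]].dropna().copy()
    complete = df.groupby(subject_col)[bin_col].nunique()
    n_bins = df[bin_col].nunique()
    keep = complete[complete == n_bins].index
    df = df[df[subject_col].isin(keep)]
    group_sizes = df.groupby(shift_col)[subject_col].nunique()
    if len(group_sizes) < 2 or (group_sizes < 2).any():
        raise ValueError("need at least 2 participants per shift group")

    aov = pg.mixed_anova(
        data=df,
        dv=value_col,
        within=bin_col,
        subject=subject_col,
        between=shift_col,
        correction=True,
    )
    aov = aov.set_index("Source")
    within_row = aov.loc[bin_col]
    inter_row = aov.loc["Interaction"]
    between_row = aov.loc[shift_col]
    terms = {
        "shift": (
            float(between_row["F"]), float(between_row["DF1"]),
            float(between_row["DF2"]), float(between_row["p_unc"]),
        ),
        "time": (
            float(within_row["F"]), float(within_row["DF1"]),
            float(within_row["DF2"]), float(within_row["p_unc"]),
        ),
        "shift:time": (
            float(inter_row["F"]), float(inter_row["DF1"]),
            float(inter_row["DF2"]), float(inter_row["p_unc"]),
        ),
    }
    spher = pg.sphericity(df, dv=value_col, subject=subject_col, within=bin_col)
    eps = float(pg.epsilon(df, dv=value_col, subject=subject_col, within=bin_col, correction="gg"))
    sphericity_met = bool(spher.pval >= alpha_sphericity)
    corrected: dict[str, tuple[float, float, float]] = {}
    if not sphericity_met:
        for term, row in (("time", within_row), ("shift:time", inter_row)):
            df1c = eps * float(row["DF1"])
            df2c = eps * float(row["DF2"])
            pc = float(sps.f.sf(float(row["F"]), df1c, df2c))
            corrected[term] = (df1c, df2c, pc)

    pairwise: dict[str, TTestResult] = {}
    shifts = sorted(df[shift_col].unique())
    for b, grp in df.groupby(bin_col, sort=True):
        x = grp.loc[grp[shift_col] == shifts[0], value_col]
        y = grp.loc[grp[shift_col] == shifts[1], value_col]
        pairwise[str(b)] = two_sample_ttest(x, y)

    return RmAnovaResult(
        terms=terms,
        mauchly_w=float(spher.W),
        mauchly_p=float(spher.pval),
        gg_epsilon=eps,
        corrected=corrected,
        sphericity_met=sphericity_met,
        pairwise=pairwise,
        n_per_group={k: int(v) for k, v in group_sizes.items()},
    )


def lmm_ema(
    data: pd.DataFrame,
    outcome: str,
    min_emas: int = 10,
    shift_col: str = "shift",
    status_col: str = "status",
    subject_col: str = "participant_id",
) -> MixedModelResult:
    """Random-intercept linear mixed model for a momentary (EMA) outcome.

    Fixed effects: shift, work status, and their interaction (treatment
    coding, reference night shift / off-day).  Fit by REML.  Participants
    with fewer than ``min_emas`` responses are excluded first.  The t
    statistics use the residual-df convention (N observations minus the
    number of fixed effects).
    """
    df = data[[subject_col, shift_col, status_col, outcome]].dropna().copy()
    counts = df.groupby(subject_col).size()
    keep = counts[counts >= min_emas].index
    n_excluded = int((counts < min_emas).sum())
    df = df[df[subject_col].isin(keep)]
    if df.groupby(shift_col)[subject_col].nunique().min() < 2 or df[shift_col].nunique() < 2:
        raise ValueError("need at least 2 participants per shift after exclusions")
    df["_y"] = df[outcome].astype(float)
    df["_day"] = (df[shift_col] == "day").astype(float)
    df["_work"] = (df[status_col] == "workday").astype(float)

    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm("_y ~ _day * _work", data=df, groups=df[subject_col])
        fit = model.fit(reml=True)
        for w in caught:
            if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
                singular = True
    k_fixed = len(fit.fe_params)
    df_resid = len(df) - k_fixed
    names = {
        "Intercept": "intercept",
        "_day": "shift[day]",
        "_work": "status[workday]",
        "_day:_work": "shift[day]:status[workday]",
    }
    fixed = {}
    for raw, term in names.items():
        est = float(fit.fe_params[raw])
        se = float(fit.bse_fe[raw])
        t = est / se
        p = float(2 * sps.t.sf(abs(t), df_resid))
        fixed[term] = (est, se, t, float(df_resid), p)
    re_var = float(fit.cov_re.iloc[0, 0])
    if re_var <= 1e-8:
        singular = True
    return MixedModelResult(
        fixed=fixed,
        random_intercept_var=re_var,
        resid_var=float(fit.scale),
        n_obs=len(df),
        n_participants=int(df[subject_col].nunique()),
        n_excluded=n_excluded,
        converged=bool(fit.converged),
        singular=singular,
    )


def std_regression(data: pd.DataFrame, outcome: str, feature: str) -> RegressionResult:
    """Standardized-β regression of a baseline score on one sensor feature.

    Model: z(outcome) ~ age[<40] + gender[female] + shift[day] + z(feature)
    + shift[day]×z(feature).  The outcome and the continuous feature are
    z-scored; binary terms are 0/1 dummies against reference levels night
    shift, male, age ≥ 40, so coefficients read as standardized βs for the
    non-reference level.  Reports per-term t and p, adjusted R², and the
    model F test.
    """
    cols = [outcome, feature, "shift", "age_group", "gender"]
    df = data[cols].dropna().copy()
    n = len(df)
    if n <= 6:
        raise ValueError("need more than 6 complete observations")
    feat = df[feature].astype(float)
    if np.var(feat) == 0:
        raise ValueError("feature has zero variance")
    df["_y"] = (df[outcome] - df[outcome].mean()) / df[outcome].std(ddof=1)
    df["_x"] = (feat - feat.mean()) / feat.std(ddof=1)
    df["_day"] = (df["shift"] == "day").astype(float)
    df["_young"] = (df["age_group"] == "<40").astype(float)
    df["_female"] = (df["gender"] == "female").astype(float)

    X = sm.add_constant(
        df[["_young", "_female", "_day", "_x"]].assign(_dayx=df["_day"] * df["_x"])
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("perfectly collinear design (terms: " + ", ".join(X.columns) + ")")
    fit = sm.OLS(df["_y"], X).fit()
    names = {
        "const": "intercept",
        "_young": "age[<40]",
        "_female": "gender[female]",
        "_day": "shift[day]",
        "_x": feature,
        "_dayx": f"shift[day]:{feature}",
    }
    terms = {
        pretty: (float(fit.params[raw]), float(fit.tvalues[raw]), float(fit.pvalues[raw]))
        for raw, pretty in names.items()
    }
    return RegressionResult(
        terms=terms,
        adj_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        f=float(fit.fvalue),
        df_model=float(fit.df_model),
        df_resid=float(fit.df_resid),
        n=n,
    )
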