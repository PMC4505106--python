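"""Statistical inference: mixed factorial ANOVA with Scheffé post-hoc and
simple effects, one-way ANOVA, and hierarchical moderated regression with
simple slopes at +/- 1 SD of the moderator.

The central model is the moderated regression of mean correct Reverse
response time on age (months) and the L-R laterality index::

    step 1:  RT = b0 + b1 * age_c + b2 * LR_c
    step 2:  RT = b0 + b1 * age_c + b2 * LR_c + b3 * age_c * LR_c

with all predictors centered on their sample means, the product formed
from the centered variables, and the step-2 gain tested via the Delta-R^2
F-test.  Standardized coefficients use beta = b * SD(x) / SD(y); the
product term is standardized by the SD of the centered product.  When the
interaction is present, the conditional (simple) slope of age at moderator
value m is ``b1 + b3 * m``, with variance
``Var(b1) + m^2 Var(b3) + 2 m Cov(b1, b3)``, evaluated at m = +/- 1 SD of
the moderator (Aiken-West procedure).

The mixed ANOVA is the classical split-plot partition for one
between-subjects factor (group) crossed with a complete within-subjects
factor (here 2 levels, e.g. R-ROI / L-ROI), using weighted marginal means;
with 2 within levels sphericity holds trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm

__all__ = [
    "AnovaResult",
    "ScheffeResult",
    "HierarchicalRegressionResult",
    "SimpleSlopesResult",
    "ModeratedRegression",
    "mixed_anova",
    "simple_effect_within",
    "oneway_anova",
    "scheffe_posthoc",
    "hierarchical_regression",
    "simple_slopes",
]


@dataclass
class AnovaEffect:
    ss: float
    df: tuple[float, float]
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    """Effect table plus retained SS/MS for audit."""

    effects: dict[str, AnovaEffect]
    ss_total: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append(
                {
                    "effect": name,
                    "SS": e.ss,
                    "df_num": e.df[0],
                    "df_den": e.df[1],
                    "MS": e.ms,
                    "F": e.F,
                    "p": e.p,
                }
            )
        return pd.DataFrame(rows)

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]


@dataclass
class ScheffeResult:
    contrasts: pd.DataFrame  # columns: group_a, group_b, estimate, F, p_adj

    def p_adj(self, a: str, b: str) -> float:
        df = self.contrasts
        hit = df[
            ((df.group_a == a) & (df.group_b == b))
            | ((df.group_a == b) & (df.group_b == a))
        ]
        return float(hit.p_adj.iloc[0])


# ---------------------------------------------------------------------------
# ANOVA


def mixed_anova(
    data: pd.DataFrame,
    group_col: str = "group",
    within_cols: tuple[str, ...] = ("right", "left"),
    subject_col: str = "participant_id",
) -> AnovaResult:
    """Mixed (split-plot) ANOVA: one between-subjects factor, one complete
    within-subjects factor whose levels are the ``within_cols`` columns.

    Every subject must have a finite value for every within level.  Returns
    between (group), within (location), interaction and both error strata.
    """
    y = data[list(within_cols)].to_numpy(dtype=float)
    if np.isnan(y).any():
        bad = data.loc[np.isnan(y).any(axis=1), subject_col].tolist()
        raise ValueError(f"missing within-level values for subjects {bad}")
    groups = data[group_col].to_numpy()
    uniq = list(pd.unique(groups))
    k, L = len(uniq), len(within_cols)
    n_sub = len(data)
    if any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("each group needs >= 2 subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[groups == g].mean() for g in uniq])
    loc_means = y.mean(axis=0)
    n_g = np.array([(groups == g).sum() for g in uniq])

    ss_group = L * float(np.sum(n_g * (group_means - grand) ** 2))
    ss_subj = L * float(
        sum(
            np.sum((subj_means[groups == g] - gm) ** 2)
            for g, gm in zip(uniq, group_means)
        )
    )
    ss_loc = n_sub * float(np.sum((loc_means - grand) ** 2))
    cell = np.array([y[groups == g].mean(axis=0) for g in uniq])  # k x L
    ss_int = float(
        np.sum(
            n_g[:, None]
            * (cell - group_means[:, None] - loc_means[None, :] + grand) ** 2
        )
    )
    # within-subject error: residual after cell means and subject effects
    resid = np.empty_like(y)
    for gi, g in enumerate(uniq):
        idx = groups == g
        resid[idx] = (
            y[idx]
            - cell[gi][None, :]
            - subj_means[idx][:, None]
            + group_means[gi]
        )
    ss_err_w = float(np.sum(resid**2))
    ss_total = float(np.sum((y - grand) ** 2))

    df_group = k - 1
    df_subj = n_sub - k
    df_loc = L - 1
    df_int = (k - 1) * (L - 1)
    df_err_w = (n_sub - k) * (L - 1)

    # degenerate strata (e.g. exactly equal within-levels) leave SS that are
    # pure float cancellation residue; judge "zero" relative to the data scale
    tiny = 1e-12 * max(ss_total, 1e-300)

    def eff(ss, dfn, dfd, ms_err):
        ms = ss / dfn
        if ms_err > tiny:
            F = ms / ms_err
            p = float(stats.f.sf(F, dfn, dfd))
        elif ss > tiny:
            F, p = np.inf, 0.0
        else:
            F, p = 0.0, 1.0
        return AnovaEffect(ss=ss, df=(dfn, dfd), ms=ms, F=F, p=p)

    ms_subj = ss_subj / df_subj
    ms_err_w = ss_err_w / df_err_w
    effects = {
        "group": eff(ss_group, df_group, df_subj, ms_subj),
        "subjects_within_group": AnovaEffect(
            ss=ss_subj, df=(df_subj, np.nan), ms=ms_subj, F=np.nan, p=np.nan
        ),
        "location": eff(ss_loc, df_loc, df_err_w, ms_err_w),
        "group_x_location": eff(ss_int, df_int, df_err_w, ms_err_w),
        "location_x_subjects": AnovaEffect(
            ss=ss_err_w, df=(df_err_w, np.nan), ms=ms_err_w, F=np.nan, p=np.nan
        ),
    }
    return AnovaResult(effects=effects, ss_total=ss_total)


def simple_effect_within(
    values_a: np.ndarray, values_b: np.ndarray
) -> AnovaResult:
    """Paired within-subject contrast inside one group: F(1, n-1) equal to
    the squared paired t statistic."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples of equal length required")
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    d = a - b
    ss_effect = n * d.mean() ** 2 / 2.0
    ss_err = float(np.sum((d - d.mean()) ** 2)) / 2.0
    ms_err = ss_err / (n - 1)
    if ms_err > 0:
        F = ss_effect / ms_err
        p = float(stats.f.sf(F, 1, n - 1))
    else:
        F, p = (np.inf, 0.0) if ss_effect > 0 else (0.0, 1.0)
    return AnovaResult(
        effects={
            "location": AnovaEffect(
                ss=ss_effect, df=(1, n - 1), ms=ss_effect, F=F, p=p
            ),
            "error": AnovaEffect(
                ss=ss_err, df=(n - 1, np.nan), ms=ms_err, F=np.nan, p=np.nan
            ),
        }
    )


def oneway_anova(values_by_group: dict[str, np.ndarray]) -> AnovaResult:
    """Between-groups one-way ANOVA with df (k-1, N-k)."""
    groups = list(values_by_group)
    arrs = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if len(groups) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    k, N = len(groups), len(allv)
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(np.sum((a - a.mean()) ** 2) for a in arrs))
    ms_b = ss_between / (k - 1)
    ms_w = ss_within / (N - k)
    F = ms_b / ms_w if ms_w > 0 else (np.inf if ss_between > 0 else 0.0)
    p = float(stats.f.sf(F, k - 1, N - k)) if np.isfinite(F) else 0.0
    return AnovaResult(
        effects={
            "group": AnovaEffect(ss=ss_between, df=(k - 1, N - k), ms=ms_b, F=F, p=p),
            "error": AnovaEffect(
                ss=ss_within, df=(N - k, np.nan), ms=ms_w, F=np.nan, p=np.nan
            ),
        },
        ss_total=ss_between + ss_within,
    )


def scheffe_posthoc(
    values_by_group: dict[str, np.ndarray], omnibus: AnovaResult | None = None
) -> ScheffeResult:
    """Scheffé-adjusted pairwise group contrasts.

    Each pair's contrast statistic is F* = t^2 / (k-1) with t computed from
    the pooled within-group MS; the adjusted p is P(F(k-1, N-k) >= F*).
    With two groups this collapses to the omnibus test.
    """
    if omnibus is None:
        omnibus = oneway_anova(values_by_group)
    groups = list(values_by_group)
    arrs = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    k = len(groups)
    N = sum(len(a) for a in arrs.values())
    mse = omnibus["error"].ms
    dfd = N - k
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            diff = arrs[a].mean() - arrs[b].mean()
            se2 = mse * (1 / len(arrs[a]) + 1 / len(arrs[b]))
            F_contrast = (diff**2 / se2) / (k - 1) if se2 > 0 else np.inf
            p_adj = float(stats.f.sf(F_contrast, k - 1, dfd))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "estimate": diff,
                    "F": F_contrast,
                    "p_adj": p_adj,
                }
            )
    return ScheffeResult(contrasts=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# hierarchical moderated regression


@dataclass
class RegressionStep:
    terms: list[str]
    b: np.ndarray                # raw coefficients incl. intercept first
    beta: np.ndarray             # standardized (NaN for intercept)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    delta_r2: float
    f_change: float
    df_change: tuple[float, float]
    p_change: float
    model_F: float
    model_df: tuple[float, float]
    model_p: float
    cov: np.ndarray
    resid_df: int

    def coef(self, term: str) -> float:
        return float(self.b[self.terms.index(term)])

    def beta_of(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def p_of(self, term: str) -> float:
        return float(self.p[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "b": self.b,
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )


@dataclass
class HierarchicalRegressionResult:
    steps: list[RegressionStep]
    centers: dict[str, float]
    sds: dict[str, float]
    sd_y: float
    n: int

    @property
    def step1(self) -> RegressionStep:
        return self.steps[0]

    @property
    def step2(self) -> RegressionStep:
        return self.steps[1]


@dataclass
class SimpleSlopesResult:
    """Conditional slope of the focal predictor at moderator = +/- 1 SD."""

    moderator_sd: float
    table: pd.DataFrame  # columns: at, slope, beta, se, t, p

    def slope_at(self, which: str) -> pd.Series:
        return self.table.set_index("at").loc[which]


def _fit_steps(y: np.ndarray, design_steps: list[tuple[list[str], np.ndarray]], sds_x: dict[str, float], sd_y: float):
    steps = []
    prev_r2 = 0.0
    prev_k = 0
    n = len(y)
    for terms, X in design_steps:
        Xc = sm.add_constant(X)
        fit = sm.OLS(y, Xc).fit()
        k = X.shape[1]
        r2 = float(fit.rsquared)
        delta = r2 - prev_r2
        q = k - prev_k
        resid_df = n - k - 1
        f_change = (delta / q) / ((1 - r2) / resid_df) if r2 < 1 else np.inf
        p_change = float(stats.f.sf(f_change, q, resid_df)) if np.isfinite(f_change) else 0.0
        beta = np.full(k + 1, np.nan)
        for j, t in enumerate(terms):
            beta[j + 1] = fit.params[j + 1] * sds_x[t] / sd_y
        steps.append(
            RegressionStep(
                terms=["intercept"] + terms,
                b=np.asarray(fit.params),
                beta=beta,
                se=np.asarray(fit.bse),
                t=np.asarray(fit.tvalues),
                p=np.asarray(fit.pvalues),
                r2=r2,
                adj_r2=float(fit.rsquared_adj),
                delta_r2=delta,
                f_change=float(f_change),
                df_change=(q, resid_df),
                p_change=p_change,
                model_F=float(fit.fvalue),
                model_df=(fit.df_model, fit.df_resid),
                model_p=float(fit.f_pvalue),
                cov=np.asarray(fit.cov_params()),
                resid_df=int(fit.df_resid),
            )
        )
        prev_r2, prev_k = r2, k
    return steps


def hierarchical_regression(
    outcome: np.ndarray,
    age_months: np.ndarray,
    lr_index: np.ndarray,
    predictor_names: tuple[str, str] = ("age_months", "lr_index"),
) -> HierarchicalRegressionResult:
    """Two-step moderated regression of ``outcome`` on centered age and
    centered laterality, adding their product in step 2."""
    y = np.asarray(outcome, dtype=float)
    x1 = np.asarray(age_months, dtype=float)
    x2 = np.asarray(lr_index, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[mask], x1[mask], x2[mask]
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, have {n}")
    name1, name2 = predictor_names
    c1, c2 = x1.mean(), x2.mean()
    x1c, x2c = x1 - c1, x2 - c2
    inter = x1c * x2c
    if x1c.std() == 0 or x2c.std() == 0:
        raise ValueError("constant predictor: model is rank deficient")
    sd = lambda v: float(np.std(v, ddof=1))
    sds_x = {name1: sd(x1c), name2: sd(x2c), f"{name1}_x_{name2}": sd(inter)}
    sd_y = sd(y)
    steps = _fit_steps(
        y,
        [
            ([name1, name2], np.column_stack([x1c, x2c])),
            (
                [name1, name2, f"{name1}_x_{name2}"],
                np.column_stack([x1c, x2c, inter]),
            ),
        ],
        sds_x,
        sd_y,
    )
    return HierarchicalRegressionResult(
        steps=steps,
        centers={name1: float(c1), name2: float(c2)},
        sds=sds_x,
        sd_y=sd_y,
        n=n,
    )


def simple_slopes(
    result: HierarchicalRegressionResult,
    focal: str = "age_months",
    moderator: str = "lr_index",
) -> SimpleSlopesResult:
    """Aiken-West simple slopes of ``focal`` at moderator = +/- 1 SD,
    from the step-2 coefficient covariance."""
    step = result.step2
    inter_term = None
    for t in step.terms:
        if "_x_" in t:
            inter_term = t
    if inter_term is None:
        raise ValueError("step-2 model has no interaction term")
    i_f = step.terms.index(focal)
    i_i = step.terms.index(inter_term)
    b_f, b_i = step.b[i_f], step.b[i_i]
    sd_m = result.sds[moderator]
    rows = []
    for label, m in (("+1sd", sd_m), ("-1sd", -sd_m)):
        slope = b_f + m * b_i
        var = step.cov[i_f, i_f] + m**2 * step.cov[i_i, i_i] + 2 * m * step.cov[i_f, i_i]
        se = float(np.sqrt(var))
        tval = slope / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(tval), step.resid_df))
        rows.append(
            {
                "at": label,
                "slope": float(slope),
                "beta": float(slope * result.sds[focal] / result.sd_y),
                "se": se,
                "t": float(tval),
                "p": p,
            }
        )
    return SimpleSlopesResult(moderator_sd=sd_m, table=pd.DataFrame(rows))


def simple_slope_by_refit(
    outcome, age_months, lr_index, m: float
) -> float:
    """Oracle route: re-center the moderator at ``m`` above its mean,
    refit step 2, and read the focal coefficient."""
    y = np.asarray(outcome, float)
    x1 = np.asarray(age_months, float) - np.mean(age_months)
    x2 = np.asarray(lr_index, float) - np.mean(lr_index) - m
    X = sm.add_constant(np.column_stack([x1, x2, x1 * x2]))
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1])


# ---------------------------------------------------------------------------
# scikit-learn estimator facade


class ModeratedRegression(RegressorMixin, BaseEstimator):
    """Two-step moderated (hierarchical) regression as an sklearn estimator.

    ``X`` has two columns, ``(focal predictor, moderator)``; ``y`` is the
    outcome.  Both predictors are centered on their sample means and the
    interaction is their centered product.  ``predict`` uses the step-2
    model.

    Attributes
    ----------
    result_ : HierarchicalRegressionResult
    coef_ : ndarray of shape (3,)
        Step-2 raw coefficients (focal, moderator, interaction).
    intercept_ : float
    simple_slopes_ : SimpleSlopesResult
    """

    def __init__(self, feature_names: tuple[str, str] = ("x", "moderator")):
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): focal and moderator")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.result_ = hierarchical_regression(
            y, X[:, 0], X[:, 1], predictor_names=self.feature_names
        )
        step2 = self.result_.step2
        self.coef_ = step2.b[1:]
        self.intercept_ = float(step2.b[0])
        self.simple_slopes_ = simple_slopes(
            self.result_,
            focal=self.feature_names[0],
            moderator=self.feature_names[1],
        )
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=float)
        c = self.result_.centers
        x1 = X[:, 0] - c[self.feature_names[0]]
        x2 = X[:, 1] - c[self.feature_names[1]]
        b = self.coef_
        return self.intercept_ + b[0] * x1 + b[1] * x2 + b[2] * x1 * x2

    def score(self, X, y):
        # R^2 of the step-2 model on the given data
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        return 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
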