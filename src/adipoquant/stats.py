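"""Cohort statistics: FRAX stratification, group comparisons, correlation
matrices, stepwise AIC interaction regression and Bland-Altman agreement.

The group-comparison layer offers both a rank-based Kruskal-Wallis test and
heteroscedasticity-robust one-way ANOVAs.  The source protocol combines
"Brown-Forsythe with Welch's correction", which are two distinct tests, so
both are computed and returned, with Welch's ANOVA designated primary.

The regression layer fits FRAX (10-year major-fracture probability, %) on
z-scored depot metrics and demographics with all two-way interactions, by
bidirectional stepwise selection under the Akaike information criterion:

    Y = alpha + sum_j beta_j x_j + sum_{j<k} gamma_jk x_j x_k + eps

BMI is excluded from the candidates (collinear with height and weight).
No strong-hierarchy constraint is imposed: an interaction may enter without
its main effects, matching the published model's structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

GROUP_ORDER = ("LOW", "MOD", "HIGH")

#: depot-metric and demographic columns offered to the regression
METRIC_COLUMNS = (
    "pdff_bmat", "pdff_mus", "pdff_sat",
    "r2star_bmat", "r2star_mus", "r2star_sat",
    "vol_bmat", "vol_mus", "vol_sat",
)
DEMOGRAPHIC_CANDIDATES = ("height", "weight", "age")
DEMOGRAPHIC_COLUMNS = ("age", "height", "weight", "bmi")


def assign_frax_group(frax: float) -> str:
    """FRAX stratum: <10 LOW, >20 HIGH, otherwise MOD.

    The published strata use strict inequalities that leave exactly 10 and 20
    unassigned; both boundaries are mapped to MOD (documented convention).
    """
    if frax < 0:
        raise ValueError("FRAX score must be non-negative")
    if frax < 10:
        return "LOW"
    if frax > 20:
        return "HIGH"
    return "MOD"


def summarize_cohort(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ("height", "weight", "bmi", "age", "frax"),
) -> pd.DataFrame:
    """Per-group min/max/range/mean/SD/CV% summary of demographic variables.

    CV% = 100 * SD / mean; a zero mean leaves CV as NaN with a warning.
    """
    rows = []
    for group, sub in cohort.groupby("group", sort=False):
        for var in variables:
            x = sub[var].to_numpy(float)
            mean = x.mean()
            sd = x.std(ddof=1) if x.size > 1 else 0.0
            if mean == 0:
                warnings.warn(f"zero mean for {var} in {group}: CV undefined",
                              stacklevel=2)
                cv = np.nan
            else:
                cv = 100.0 * sd / mean
            rows.append({
                "group": group, "variable": var, "n": x.size,
                "min": x.min(), "max": x.max(), "range": x.max() - x.min(),
                "mean": mean, "sd": sd, "cv_pct": cv,
            })
    return pd.DataFrame(rows)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    allv = np.concatenate(groups)
    if allv.size < 3:
        raise ValueError("need >= 3 observations in total")
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class AnovaResult:
    statistic: float
    df_num: float
    df_den: float
    p_value: float


def welch_anova(*groups) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA (unequal variances)."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n = np.array([len(g) for g in groups], float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    scale = max(np.abs(np.concatenate(groups)).max(), 1e-300)
    if np.all(v <= (1e-12 * scale) ** 2):  # numerically constant groups
        if np.ptp(m) <= 1e-12 * scale:
            return AnovaResult(0.0, k - 1.0, np.inf, 1.0)
        return AnovaResult(np.inf, k - 1.0, np.inf, 0.0)
    w = n / v
    sw = w.sum()
    mw = (w * m).sum() / sw
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / sw) ** 2 / (n - 1)).sum() / (k**2 - 1)
    f = num / (1 + 2 * (k - 2) * tmp)
    df2 = 1.0 / (3 * tmp)
    p = float(sps.f.sf(f, k - 1, df2))
    return AnovaResult(float(f), float(k - 1), float(df2), p)


def brown_forsythe_anova(*groups) -> AnovaResult:
    """Brown-Forsythe F* test for equal means under unequal variances."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n = np.array([len(g) for g in groups], float)
    N = n.sum()
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    grand = np.concatenate(groups).mean()
    num = (n * (m - grand) ** 2).sum()
    ci = (1 - n / N) * v
    den = ci.sum()
    scale = max(np.abs(np.concatenate(groups)).max(), 1e-300)
    if den <= (1e-12 * scale) ** 2:
        if num <= (1e-12 * scale) ** 2:
            return AnovaResult(0.0, k - 1.0, np.inf, 1.0)
        return AnovaResult(np.inf, k - 1.0, np.inf, 0.0)
    f = num / den
    df2 = 1.0 / ((ci / den) ** 2 / (n - 1)).sum()
    p = float(sps.f.sf(f, k - 1, df2))
    return AnovaResult(float(f), float(k - 1), float(df2), p)


def heteroscedastic_anova(*groups) -> dict[str, AnovaResult]:
    """Both Welch's ANOVA (primary) and the Brown-Forsythe F*."""
    return {"welch": welch_anova(*groups),
            "brown_forsythe": brown_forsythe_anova(*groups)}


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # |r| > 0.5 and p < 0.05


def pearson_matrix(
    cohort: pd.DataFrame,
    group: str | None = None,
    columns: tuple[str, ...] = METRIC_COLUMNS + ("age", "height", "weight",
                                                 "bmi", "frax"),
    r_cut: float = 0.5,
    p_cut: float = 0.05,
) -> CorrelationResult:
    """Pairwise Pearson r and p within one group (or the whole cohort).

    p values come from the t transform under the zero-correlation null; the
    joint criterion |r| > 0.5 and p < 0.05 flags "significant" correlations.
    Constant columns yield NaN entries with a warning.
    """
    sub = cohort if group is None else cohort[cohort["group"] == group]
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 subjects per group")
    X = sub[list(columns)].to_numpy(float)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant columns {[c for c, k in zip(columns, const) if k]}: "
            "correlations undefined", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * sps.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    cols = list(columns)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sig = (rdf.abs() > r_cut) & (pdf < p_cut)
    np.fill_diagonal(sig.values, False)
    return CorrelationResult(r=rdf, p=pdf, significant=sig)


# ---------------------------------------------------------------------------
# stepwise AIC interaction regression

@dataclass
class StepwiseFit:
    selected_terms: list[str]
    coefficients: pd.DataFrame     # term, estimate, se, p, ci_low, ci_high
    aic_trace: list[float]
    r2: float
    r2_adjusted: float
    cv_scores: list[float]
    response: str = "frax"
    meta: dict = field(default_factory=dict)


def _gaussian_aic(rss: float, n: int, n_params: int, aicc: bool = False) -> float:
    """AIC = 2k - 2logL with the Gaussian profile likelihood (statsmodels
    convention: k counts regression parameters including the intercept)."""
    rss = max(rss, 1e-300)
    llf = -n / 2.0 * (np.log(2 * np.pi * rss / n) + 1.0)
    aic = 2.0 * n_params - 2.0 * llf
    if aicc:
        denom = n - n_params - 1
        if denom > 0:
            aic += 2.0 * n_params * (n_params + 1) / denom
    return aic


def build_design(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...] = METRIC_COLUMNS + DEMOGRAPHIC_CANDIDATES,
    include_interactions: bool = True,
) -> pd.DataFrame:
    """z-scored main effects plus all pairwise products of the z-scores.

    Exactly collinear candidates (duplicate columns after z-scoring) are
    dropped with a warning, keeping the earlier-listed one.
    """
    Z = {}
    for col in predictors:
        x = cohort[col].to_numpy(float)
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"constant candidate {col} dropped", stacklevel=2)
            continue
        Z[col] = (x - x.mean()) / sd
    names = list(Z)
    kept = []
    for i, a in enumerate(names):
        dup = False
        for b in kept:
            if np.allclose(Z[a], Z[b]) or np.allclose(Z[a], -Z[b]):
                warnings.warn(
                    f"candidate {a} exactly collinear with {b}: dropped",
                    stacklevel=2)
                dup = True
                break
        if not dup:
            kept.append(a)
    design = {k: Z[k] for k in kept}
    if include_interactions:
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                design[f"{a}:{b}"] = Z[a] * Z[b]
    return pd.DataFrame(design, index=cohort.index)


def _fit_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rss.size == 0:  # rank-deficient: compute explicitly
        rss_val = float(((y - X @ coef) ** 2).sum())
    else:
        rss_val = float(rss[0])
    return rss_val


def stepwise_interaction_fit(
    cohort: pd.DataFrame,
    response: str = "frax",
    predictors: tuple[str, ...] = METRIC_COLUMNS + DEMOGRAPHIC_CANDIDATES,
    include_interactions: bool = True,
    forced_terms: tuple[str, ...] = (),
    k: int = 5,
    seed: int | None = 0,
    use_aicc: bool = False,
    alpha_enter: float = 0.05,
    max_steps: int = 200,
) -> StepwiseFit:
    """Bidirectional stepwise selection under AIC, with k-fold CV diagnostics.

    Starting from the intercept-only model (plus any ``forced_terms``), the
    single add or remove move that lowers AIC most is applied until no move
    lowers it.  Because the best of m candidate additions is selected at each
    step, a raw "AIC decreased" rule would admit a noise term almost surely
    once m is large (the best of m chi-square(1) improvements easily exceeds
    the 2-point penalty); additions therefore must clear a
    multiplicity-adjusted margin equivalent to a Bonferroni alpha_enter/m
    entry test on the AIC scale.  Removals use the plain AIC comparison.

    The final model is refit with statsmodels OLS for standard errors,
    p values and 95% CIs; the selected structure is then scored by k-fold
    cross-validation (per-fold test R^2).
    """
    design = build_design(cohort, predictors, include_interactions)
    y = cohort[response].to_numpy(float)
    n = len(y)
    if n <= len(predictors):
        raise ValueError("need more subjects than initially considered terms")

    selected = [t for t in forced_terms if t in design.columns]
    candidates = [c for c in design.columns if c not in selected]

    def aic_of(terms: list[str]) -> float:
        X = np.column_stack([np.ones(n)] + [design[t].to_numpy() for t in terms])
        return _gaussian_aic(_fit_rss(X, y), n, len(terms) + 1, use_aicc)

    current = aic_of(selected)
    trace = [current]
    for _ in range(max_steps):
        # entry margin: chi2 quantile of the Bonferroni-corrected level,
        # re-expressed as a required AIC drop (2 is the nominal penalty)
        m = max(len(candidates), 1)
        add_margin = max(sps.chi2.isf(min(alpha_enter / m, 1.0), 1) - 2.0, 0.0)
        best_aic, best_move = current, None
        for t in candidates:
            a = aic_of(selected + [t])
            if a < current - add_margin and a < best_aic - 1e-10:
                best_aic, best_move = a, ("add", t)
        for t in selected:
            if t in forced_terms:
                continue
            a = aic_of([s for s in selected if s != t])
            if a < best_aic - 1e-10:
                best_aic, best_move = a, ("remove", t)
        if best_move is None:
            break
        op, t = best_move
        if op == "add":
            selected.append(t)
            candidates.remove(t)
        else:
            selected.remove(t)
            candidates.append(t)
        current = best_aic
        trace.append(current)

    X = sm.add_constant(design[selected], has_constant="add") if selected else (
        pd.DataFrame({"const": np.ones(n)}, index=cohort.index))
    ols = sm.OLS(y, X).fit()
    ci = ols.conf_int(alpha=0.05)
    coef = pd.DataFrame({
        "term": X.columns,
        "estimate": ols.params.values,
        "se": ols.bse.values,
        "p": ols.pvalues.values,
        "ci_low": np.asarray(ci)[:, 0],
        "ci_high": np.asarray(ci)[:, 1],
    })

    cv_scores: list[float] = []
    if selected and k >= 2:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        Xd = design[selected].to_numpy()
        for fold in folds:
            test = np.zeros(n, bool)
            test[fold] = True
            Xtr = np.column_stack([np.ones((~test).sum()), Xd[~test]])
            Xte = np.column_stack([np.ones(test.sum()), Xd[test]])
            beta, *_ = np.linalg.lstsq(Xtr, y[~test], rcond=None)
            pred = Xte @ beta
            ss_res = float(((y[test] - pred) ** 2).sum())
            ss_tot = float(((y[test] - y[test].mean()) ** 2).sum())
            cv_scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan)

    return StepwiseFit(
        selected_terms=selected,
        coefficients=coef,
        aic_trace=trace,
        r2=float(ols.rsquared) if selected else 0.0,
        r2_adjusted=float(ols.rsquared_adj) if selected else 0.0,
        cv_scores=cv_scores,
        response=response,
        meta={"n": n, "k_folds": k, "aicc": use_aicc,
              "n_candidates": design.shape[1]},
    )


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(predicted, actual) -> BlandAltman:
    """Agreement between predictions and observations.

    bias = mean(pred - actual); limits of agreement = bias +/- 1.96 SD(diff).
    """
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    if predicted.shape != actual.shape or predicted.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    diffs = predicted - actual
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(predicted + actual) / 2.0,
        diffs=diffs,
    )
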