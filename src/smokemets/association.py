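"""Adjusted odds ratios, trend tests, stepwise covariate selection.

Exposure categories are dummy-coded with never smokers as the reference;
odds ratios are exponentiated maximum-likelihood logistic coefficients
with Wald 95% confidence intervals (multiplier 1.96).  The linear-trend
test replaces the categorical exposure with each participant's category
median and reports the Wald p-value of that single continuous term.
Covariate selection is classical forward-with-backward-elimination
stepwise on likelihood-ratio p-values (entry p < 0.05, removal p > 0.10).

Maximum-likelihood fitting is delegated to ``statsmodels`` (Newton
iterations, coefficient tolerance 1e-8, at most 100 iterations; the
reported covariance is the inverse observed information).  Complete or
quasi-complete separation and rank deficiency raise explicit diagnostics
instead of returning unstable estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .exposure import ExposureCoding

__all__ = [
    "LogisticFit",
    "AssociationTable",
    "SeparationError",
    "RankDeficiencyError",
    "fit_logistic",
    "category_association",
    "trend_test",
    "stepwise_select",
    "descriptive_table",
    "crude_or",
    "build_design",
]

Z95 = 1.96


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood Bernoulli-logit fit."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n: int
    converged: bool

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def wald_p(self, term: str) -> float:
        z = self.params[term] / self.se()[term]
        return float(2 * scipy.stats.norm.sf(abs(z)))

    def or_ci(self, term: str) -> tuple:
        b = self.params[term]
        s = self.se()[term]
        return (float(np.exp(b)), float(np.exp(b - Z95 * s)), float(np.exp(b + Z95 * s)))

    def joint_wald(self, terms: Sequence[str]) -> tuple:
        """Joint Wald chi-square statistic and p for a set of terms."""
        idx = [list(self.params.index).index(t) for t in terms]
        b = self.params.to_numpy()[idx]
        V = self.cov.to_numpy()[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        p = float(scipy.stats.chi2.sf(stat, df=len(terms)))
        return stat, p


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list:
    """Columns made redundant by earlier ones (greedy Gram-Schmidt on the
    Gram matrix; names the later column of each dependent pair)."""
    G = X.T @ X
    scale = np.sqrt(np.diag(G))
    scale[scale == 0] = 1.0
    G = G / scale[:, None] / scale[None, :]
    kept: list = []
    bad: list = []
    for j in range(G.shape[0]):
        if np.isclose(G[j, j], 0.0):
            bad.append(names[j])
            continue
        if kept:
            sub = G[np.ix_(kept, kept)]
            g = G[np.ix_(kept, [j])]
            resid = G[j, j] - (g.T @ np.linalg.lstsq(sub, g, rcond=None)[0]).item()
        else:
            resid = G[j, j]
        if resid < 1e-10:
            bad.append(names[j])
        else:
            kept.append(j)
    return bad


def fit_logistic(outcome: Sequence, design: pd.DataFrame) -> LogisticFit:
    """Fit a Bernoulli-logit model by maximum likelihood.

    ``design`` must already contain any intercept column.  Raises
    :class:`RankDeficiencyError` naming the collinear terms, a
    ``ValueError`` when the outcome has a single class, and
    :class:`SeparationError` on (quasi-)complete separation.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.to_numpy(dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome and design lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    bad = _collinear_columns(X, list(design.columns))
    if bad:
        raise RankDeficiencyError(f"design is rank deficient; collinear terms: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
            if not res.mle_retvals.get("converged", False):
                # Newton can oscillate on flat likelihoods; one BFGS pass
                # resolves genuinely fittable models
                res = sm.Logit(y, X).fit(
                    method="bfgs", maxiter=500, disp=0, start_params=res.params
                )
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation detected in logistic fit: {exc}") from exc
    beta = res.params
    p = 1.0 / (1.0 + np.exp(-X @ beta))
    grad = X.T @ (y - p)
    if not res.mle_retvals.get("converged", False) or np.abs(beta).max() > 50:
        raise SeparationError(
            "logistic fit did not converge to a finite optimum "
            "(quasi-complete separation or degenerate design)"
        )
    if np.linalg.norm(grad) > 1e-6 * max(1.0, y.shape[0] / 1000.0):
        raise SeparationError(f"score norm {np.linalg.norm(grad):.3g} at optimum")
    names = list(design.columns)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(res.cov_params(), index=names, columns=names),
        llf=float(res.llf),
        n=int(y.shape[0]),
        converged=True,
    )


def build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    add_const: bool = True,
) -> pd.DataFrame:
    """Numeric design columns for the named covariates.

    Numeric covariates enter as-is (age and BMI are continuous).  String
    or categorical covariates are dummy-coded with the most frequent level
    as the reference.
    """
    cols = {}
    if add_const:
        cols["const"] = np.ones(len(df))
    for c in covariates:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            cols[c] = s.to_numpy(dtype=float)
        else:
            ref = s.value_counts().idxmax()
            for level in sorted(set(s.dropna().astype(str)) - {str(ref)}):
                cols[f"{c}[{level}]"] = (s.astype(str) == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _category_design(
    df: pd.DataFrame,
    coding: ExposureCoding,
    value_col: str,
    ever_col: str,
    covariates: Sequence[str],
) -> tuple:
    cats = coding.assign(df[value_col].to_numpy(), df[ever_col].to_numpy(dtype=bool))
    design = build_design(df, covariates)
    dummy_names = []
    for lab in coding.labels[1:]:
        name = f"exposure[{lab}]"
        design.insert(len(dummy_names) + 1, name, (np.asarray(cats) == lab).astype(float))
        dummy_names.append(name)
    return cats, design, dummy_names


@dataclass(frozen=True)
class AssociationTable:
    """Per-category counts, adjusted ORs and 95% CIs, plus a trend p."""

    scheme: str
    reference: str
    table: pd.DataFrame  # columns: category, n_cases, n_total, odds_ratio, ci_low, ci_high
    trend_p: float
    adjusted_for: tuple
    fit: Optional[LogisticFit] = field(default=None, repr=False, compare=False)

    def to_text_rows(self) -> pd.DataFrame:
        """Report shape: "MetS (+)/All" and "OR (95%CI)" strings."""
        t = self.table
        out = pd.DataFrame({"category": t["category"]})
        out["mets_pos/all"] = [f"{c}/{n}" for c, n in zip(t["n_cases"], t["n_total"])]
        out["or_95ci"] = [
            "reference" if cat == self.reference else f"{o:.2f} ({lo:.2f}-{hi:.2f})"
            for cat, o, lo, hi in zip(t["category"], t["odds_ratio"], t["ci_low"], t["ci_high"])
        ]
        return out


def category_association(
    df: pd.DataFrame,
    coding: ExposureCoding,
    value_col: str,
    ever_col: str,
    outcome_col: str,
    covariates: Sequence[str] = (),
    with_trend: bool = True,
) -> AssociationTable:
    """Adjusted ORs of the outcome across exposure categories.

    Never smokers are the reference (OR fixed at 1); each non-reference
    category gets ``exp(beta)`` with a Wald 95% CI.  ``trend_p`` is the
    median-score trend test when the coding carries category medians.
    """
    cats, design, dummies = _category_design(df, coding, value_col, ever_col, covariates)
    counts = pd.Series(cats).value_counts()
    empty = [lab for lab in coding.labels if counts.get(lab, 0) == 0]
    if empty:
        raise ValueError(f"empty exposure categories: {empty}")
    y = df[outcome_col].to_numpy(dtype=float)
    fit = fit_logistic(y, design)

    rows = []
    for lab in coding.labels:
        in_cat = np.asarray(cats == lab)
        if lab == coding.reference:
            orr, lo, hi = 1.0, np.nan, np.nan
        else:
            orr, lo, hi = fit.or_ci(f"exposure[{lab}]")
        rows.append(
            dict(
                category=lab,
                n_cases=int(y[in_cat].sum()),
                n_total=int(in_cat.sum()),
                odds_ratio=orr,
                ci_low=lo,
                ci_high=hi,
            )
        )
    trend_p = np.nan
    if with_trend and coding.category_medians:
        try:
            trend_p = trend_test(df, coding, value_col, ever_col, outcome_col, covariates)
        except ValueError:
            trend_p = np.nan
    return AssociationTable(
        scheme=coding.scheme,
        reference=coding.reference,
        table=pd.DataFrame(rows),
        trend_p=trend_p,
        adjusted_for=tuple(covariates),
        fit=fit,
    )


def trend_test(
    df: pd.DataFrame,
    coding: ExposureCoding,
    value_col: str,
    ever_col: str,
    outcome_col: str,
    covariates: Sequence[str] = (),
) -> float:
    """Linear-trend p: category medians entered as one continuous term."""
    scores = coding.median_scores(df[value_col].to_numpy(), df[ever_col].to_numpy(dtype=bool))
    if len(np.unique(scores)) < 2:
        raise ValueError("trend test needs at least 2 distinct category medians")
    design = build_design(df, covariates)
    design.insert(1, "trend_score", scores)
    fit = fit_logistic(df[outcome_col].to_numpy(dtype=float), design)
    return fit.wald_p("trend_score")


def _candidate_columns(df: pd.DataFrame, name: str) -> pd.DataFrame:
    return build_design(df, [name], add_const=False)


def _lr_p(fit_full: LogisticFit, fit_reduced: LogisticFit, df_diff: int) -> float:
    stat = 2 * (fit_full.llf - fit_reduced.llf)
    return float(scipy.stats.chi2.sf(max(stat, 0.0), df=df_diff))


def stepwise_select(
    df: pd.DataFrame,
    outcome_col: str,
    candidates: Sequence[str],
    p_in: float = 0.05,
    p_out: float = 0.10,
) -> list:
    """Forward stepwise selection with backward elimination.

    At each entry step the most significant remaining candidate joins the
    model if its likelihood-ratio p-value is below ``p_in``; after every
    entry, included terms whose drop-one LR p exceeds ``p_out`` are
    removed.  Categorical candidates enter and leave as whole dummy
    blocks.  ``p_in < p_out`` guarantees termination.  Candidates whose
    columns are collinear with the current model never enter.
    """
    if p_in >= p_out:
        raise ValueError("p_in must be < p_out to guarantee termination")
    y = df[outcome_col].to_numpy(dtype=float)
    blocks = {name: _candidate_columns(df, name) for name in candidates}

    def fit_terms(terms: Sequence[str]) -> LogisticFit:
        design = pd.concat(
            [pd.DataFrame({"const": np.ones(len(df))}, index=df.index)]
            + [blocks[t] for t in terms],
            axis=1,
        )
        return fit_logistic(y, design)

    selected: list = []
    current_fit = fit_terms(selected)
    while True:
        best_name, best_p, best_fit = None, np.inf, None
        for name in candidates:
            if name in selected:
                continue
            try:
                fit = fit_terms(selected + [name])
            except (RankDeficiencyError, SeparationError):
                continue
            p = _lr_p(fit, current_fit, blocks[name].shape[1])
            if p < best_p:
                best_name, best_p, best_fit = name, p, fit
        if best_name is None or best_p >= p_in:
            break
        selected.append(best_name)
        current_fit = best_fit
        # backward elimination pass
        removed = True
        while removed and len(selected) > 1:
            removed = False
            worst_name, worst_p = None, -np.inf
            for name in selected:
                reduced = fit_terms([t for t in selected if t != name])
                p = _lr_p(current_fit, reduced, blocks[name].shape[1])
                if p > worst_p:
                    worst_name, worst_p = name, p
            if worst_name is not None and worst_p > p_out and worst_name != best_name:
                selected.remove(worst_name)
                current_fit = fit_terms(selected)
                removed = True
    return selected


def descriptive_table(
    df: pd.DataFrame,
    group_col: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Group comparison: mean +/- SD with t-tests, n (%) with chi-square.

    Returns one row per continuous variable and per categorical level,
    with per-group summaries, the p-value of the group comparison and a
    validity flag (chi-square is flagged invalid when an expected cell
    count is zero).
    """
    groups = [g for g, _ in df.groupby(group_col, observed=True)]
    if len(groups) != 2:
        raise ValueError(f"descriptive_table expects 2 groups, found {len(groups)}")
    ga = df[df[group_col] == groups[0]]
    gb = df[df[group_col] == groups[1]]
    rows = []
    for var in continuous:
        a = ga[var].dropna().to_numpy(dtype=float)
        b = gb[var].dropna().to_numpy(dtype=float)
        _, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            dict(
                variable=var,
                level="",
                **{
                    f"{groups[0]}": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                    f"{groups[1]}": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                },
                p_value=float(p),
                test="t",
                valid=True,
            )
        )
    for var in categorical:
        tab = pd.crosstab(df[var], df[group_col])
        tab = tab.reindex(columns=groups, fill_value=0)
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.to_numpy().sum()
        valid = bool((expected > 0).all())
        if valid:
            chi2, p, _, _ = scipy.stats.chi2_contingency(tab.to_numpy(), correction=False)
        else:
            p = np.nan
        for level in tab.index:
            rows.append(
                dict(
                    variable=var,
                    level=str(level),
                    **{
                        f"{g}": f"{tab.loc[level, g]} ({100 * tab.loc[level, g] / tab[g].sum():.2f})"
                        for g in groups
                    },
                    p_value=float(p) if valid else np.nan,
                    test="chi2",
                    valid=valid,
                )
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrudeOddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool


def crude_or(a: float, b: float, c: float, d: float) -> CrudeOddsRatio:
    """Unadjusted OR from a 2x2 table with a Woolf (log) 95% CI.

    Cells are (exposed cases, exposed non-cases, unexposed cases,
    unexposed non-cases).  Zero cells get a 0.5 continuity correction and
    the result is flagged; an all-zero margin is undefined.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be >= 0")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a zero margin leaves the odds ratio undefined")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    orr = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return CrudeOddsRatio(
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - Z95 * se)),
        ci_high=float(np.exp(np.log(orr) + Z95 * se)),
        continuity_corrected=corrected,
    )
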