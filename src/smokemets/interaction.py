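"""Effect modification: stratified ORs, multiplicative and additive interaction.

Multiplicative interaction is tested with a joint Wald chi-square on the
exposure-category x modifier product terms of one pooled logistic model
(df = number of non-reference categories).  Additive interaction uses the
relative excess risk due to interaction,

    RERI = OR11 - OR10 - OR01 + 1,

from a single model with indicators for exposed-only, modifier-only and
jointly exposed; RERI = 0 under exact additivity of the two effects.  Its
95% CI comes from the delta method on the three log-OR coefficients and
their estimated covariance (Hosmer-Lemeshow construction); a bootstrap CI
is available behind a flag for cross-checking.  With odds ratios, RERI
approximates risk-ratio additivity only when the outcome is reasonably
rare in every exposure-modifier cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import (
    Z95,
    LogisticFit,
    build_design,
    category_association,
    fit_logistic,
)
from .exposure import ExposureCoding

__all__ = [
    "InteractionResult",
    "ReriResult",
    "multiplicative_interaction",
    "reri",
    "stratified_associations",
]


@dataclass(frozen=True)
class ReriResult:
    reri: float
    ci_low: float
    ci_high: float
    or10: float
    or01: float
    or11: float
    fit: Optional[LogisticFit] = None


@dataclass(frozen=True)
class InteractionResult:
    """One modifier's interaction analysis (stratified report row)."""

    modifier: str
    strata: dict  # stratum label -> AssociationTable
    wald_interaction_p: float
    reri: ReriResult


def multiplicative_interaction(
    df: pd.DataFrame,
    coding: ExposureCoding,
    value_col: str,
    ever_col: str,
    modifier_col: str,
    outcome_col: str,
    covariates: Sequence[str] = (),
    verbose: bool = False,
):
    """Joint Wald p for exposure-category x modifier product terms.

    ``modifier_col`` must be binary (0/1 or two levels).  Returns the
    joint p; with ``verbose=True`` returns ``(p, per_term_p)``.
    """
    mod = _binary_series(df[modifier_col], modifier_col)
    cats = coding.assign(df[value_col].to_numpy(), df[ever_col].to_numpy(dtype=bool))
    design = build_design(df, covariates)
    product_terms = []
    for lab in coding.labels[1:]:
        in_cat = (np.asarray(cats) == lab).astype(float)
        if not _cells_populated(df[outcome_col], in_cat, mod):
            raise ValueError(
                f"empty or outcome-degenerate cell for category {lab!r} x {modifier_col!r}"
            )
        design[f"exposure[{lab}]"] = in_cat
        design[f"exposure[{lab}]:{modifier_col}"] = in_cat * mod
        product_terms.append(f"exposure[{lab}]:{modifier_col}")
    design[modifier_col] = mod
    fit = fit_logistic(df[outcome_col].to_numpy(dtype=float), design)
    _, joint_p = fit.joint_wald(product_terms)
    if verbose:
        return joint_p, {t: fit.wald_p(t) for t in product_terms}
    return joint_p


def _binary_series(s: pd.Series, name: str) -> np.ndarray:
    vals = pd.unique(s.dropna())
    if len(vals) != 2:
        raise ValueError(f"modifier {name!r} must take exactly 2 values, found {len(vals)}")
    ref = sorted(vals, key=str)[0]
    return (s != ref).to_numpy(dtype=float)


def _cells_populated(y: pd.Series, in_cat: np.ndarray, mod: np.ndarray) -> bool:
    for m in (0.0, 1.0):
        if (in_cat * (mod == m)).sum() == 0:
            return False
    return True


def reri(
    df: pd.DataFrame,
    ever_col: str,
    modifier_col: str,
    outcome_col: str,
    covariates: Sequence[str] = (),
    n_boot: int = 0,
    seed: int = 0,
) -> ReriResult:
    """Relative excess risk due to interaction with a delta-method 95% CI.

    The exposure is dichotomous (never vs ever smoking).  One logistic
    model carries indicators for (exposed only), (modifier only) and
    (both) plus covariates; RERI = OR11 - OR10 - OR01 + 1.  The CI uses
    the delta-method gradient (OR11, -OR10, -OR01) on the coefficient
    covariance; ``n_boot > 0`` switches to a nonparametric bootstrap
    percentile CI instead.  RERI is symmetric in which factor is called
    the exposure and which the modifier.
    """
    e = df[ever_col].to_numpy(dtype=float)
    m = _binary_series(df[modifier_col], modifier_col)
    y = df[outcome_col].to_numpy(dtype=float)
    for ei, mi in [(1, 0), (0, 1), (1, 1), (0, 0)]:
        if ((e == ei) & (m == mi)).sum() == 0:
            raise ValueError(f"empty exposure x modifier cell (exposure={ei}, modifier={mi})")

    def one_fit(frame_idx: np.ndarray) -> tuple:
        design = build_design(df.iloc[frame_idx], covariates)
        ee, mm = e[frame_idx], m[frame_idx]
        design.insert(1, "exp_only", ee * (1 - mm))
        design.insert(2, "mod_only", (1 - ee) * mm)
        design.insert(3, "both", ee * mm)
        fit = fit_logistic(y[frame_idx], design)
        b10, b01, b11 = (fit.params[t] for t in ("exp_only", "mod_only", "both"))
        return fit, float(np.exp(b10)), float(np.exp(b01)), float(np.exp(b11))

    all_idx = np.arange(len(df))
    fit, or10, or01, or11 = one_fit(all_idx)
    reri_hat = or11 - or10 - or01 + 1.0

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(df), len(df))
            try:
                _, o10, o01, o11 = one_fit(idx)
            except Exception:
                continue
            draws.append(o11 - o10 - o01 + 1.0)
        lo, hi = np.percentile(draws, [2.5, 97.5])
    else:
        terms = ["exp_only", "mod_only", "both"]
        V = fit.cov.loc[terms, terms].to_numpy()
        grad = np.array([-or10, -or01, or11])
        var = float(grad @ V @ grad)
        lo = reri_hat - Z95 * np.sqrt(var)
        hi = reri_hat + Z95 * np.sqrt(var)
    return ReriResult(
        reri=float(reri_hat),
        ci_low=float(lo),
        ci_high=float(hi),
        or10=or10,
        or01=or01,
        or11=or11,
        fit=fit,
    )


def _stratum_estimable(
    sub: pd.DataFrame, covariates: Sequence[str], modifier_col: str, outcome_col: str
) -> list:
    """Covariates safe to adjust for inside one stratum.

    Drops the modifier itself, constants, and categorical covariates with
    a level that carries only cases or only non-cases in the stratum —
    such levels quasi-separate the fit.
    """
    keep = []
    for c in covariates:
        if c == modifier_col or sub[c].nunique() <= 1:
            continue
        s = sub[c]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            keep.append(c)
        else:
            tab = pd.crosstab(s, sub[outcome_col])
            if tab.shape[1] == 2 and (tab.to_numpy() > 0).all():
                keep.append(c)
    return keep


def stratified_associations(
    df: pd.DataFrame,
    coding: ExposureCoding,
    value_col: str,
    ever_col: str,
    modifier_col: str,
    outcome_col: str,
    covariates: Sequence[str] = (),
) -> dict:
    """Independent per-stratum category associations (report rows)."""
    out = {}
    for level, sub in df.groupby(modifier_col, observed=True):
        cov = _stratum_estimable(sub, covariates, modifier_col, outcome_col)
        try:
            out[str(level)] = category_association(
                sub, coding, value_col, ever_col, outcome_col, cov
            )
        except ValueError as exc:
            raise ValueError(f"stratum {modifier_col}={level!r}: {exc}") from exc
    return out


def interaction_analysis(
    df: pd.DataFrame,
    coding: ExposureCoding,
    value_col: str,
    ever_col: str,
    modifier_col: str,
    outcome_col: str,
    covariates: Sequence[str] = (),
) -> InteractionResult:
    """Full Table-4-style row: strata, joint Wald p, and RERI."""
    strata = stratified_associations(
        df, coding, value_col, ever_col, modifier_col, outcome_col, covariates
    )
    wald_p = multiplicative_interaction(
        df, coding, value_col, ever_col, modifier_col, outcome_col, covariates
    )
    rr = reri(df, ever_col, modifier_col, outcome_col, covariates)
    return InteractionResult(
        modifier=modifier_col, strata=strata, wald_interaction_p=float(wald_p), reri=rr
    )
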