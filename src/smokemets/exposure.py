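"""Life-course cigarette-smoking exposure metrics.

The central quantity is the comprehensive smoking index (CSI), a single
scalar summarising lifetime exposure from three questionnaire dimensions:
smoking intensity ``int`` (cigarettes/day), duration ``dur`` (years) and
time since cessation ``tsc`` (years).  Exposure decays exponentially with
half-life ``tau`` and the most recent ``delta`` years are excluded (lagged)
because very recent smoking is assumed not yet to affect the outcome:

    CSI = (1 - 0.5**(dur*/tau)) * 0.5**(tsc*/tau) * ln(int + 1)

with ``tsc* = max(tsc - delta, 0)`` and
``dur* = max(dur + tsc - delta, 0) - tsc*``.

The module also provides pack-years, the lagged ("discounted") exposure
variant used for reverse-causation sensitivity analyses, and categorical
codings of the continuous exposures (fixed intensity bins, data-dependent
tertiles among ever smokers) with per-category medians for trend tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SmokingStatus",
    "SmokingHistory",
    "CsiParameters",
    "ExposureCoding",
    "compute_csi",
    "csi_values",
    "compute_pack_years",
    "apply_sensitivity_lag",
    "make_coding",
]

#: Smoking deemed to require more than one year of smoking; shorter
#: exposure counts as never-smoking.
EVER_SMOKER_MIN_YEARS = 1.0


class SmokingStatus(str, Enum):
    NEVER = "never"
    FORMER = "former"
    CURRENT = "current"


@dataclass(frozen=True)
class SmokingHistory:
    """One participant's smoking history at the index date.

    Invariants (enforced at construction):

    * never smokers carry zero intensity, duration and time since cessation;
    * ever smokers (former or current) smoked for more than one year;
    * current smokers smoked within the year before the index date
      (``time_since_cessation`` < 1, treated as 0 when scoring);
    * former smokers quit more than one year before the index date.
    """

    status: SmokingStatus
    intensity: float = 0.0
    duration: float = 0.0
    time_since_cessation: float = 0.0
    start_age: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", SmokingStatus(self.status))
        for name in ("intensity", "duration", "time_since_cessation"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        s = self.status
        if s is SmokingStatus.NEVER:
            if self.intensity != 0 or self.duration != 0 or self.time_since_cessation != 0:
                raise ValueError("never smokers must have zero intensity/duration/tsc")
        else:
            if self.duration <= EVER_SMOKER_MIN_YEARS:
                raise ValueError(
                    "ever smokers must have smoked for more than "
                    f"{EVER_SMOKER_MIN_YEARS:g} year(s); got duration={self.duration!r}"
                )
            if s is SmokingStatus.CURRENT and self.time_since_cessation >= 1:
                raise ValueError("current smokers must have time_since_cessation < 1")
            if s is SmokingStatus.FORMER and self.time_since_cessation < 1:
                raise ValueError("former smokers must have time_since_cessation >= 1")

    @property
    def is_ever(self) -> bool:
        return self.status is not SmokingStatus.NEVER

    def check_age_consistency(self, age: float) -> None:
        """Raise if start age + duration + cessation time exceeds ``age``."""
        if self.start_age is None:
            return
        total = self.start_age + self.duration + self.time_since_cessation
        if total > age + 1e-9:
            raise ValueError(
                f"smoking timeline ({total:.2f} y) exceeds age at index ({age:.2f} y)"
            )


@dataclass(frozen=True)
class CsiParameters:
    """CSI shape parameters.

    ``tau`` is the exposure half-life in years and ``delta`` the lag in
    years excluded immediately before the index date; both are fixed a
    priori (25 and 0.5 y).  ``sensitivity_lag`` discounts an additional
    window (in years) before the index date — set to 3 for the
    reverse-causation sensitivity analysis, 0 otherwise.
    """

    tau: float = 25.0
    delta: float = 0.5
    sensitivity_lag: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.delta < 0 or self.sensitivity_lag < 0:
            raise ValueError("delta and sensitivity_lag must be >= 0")


DEFAULT_CSI_PARAMS = CsiParameters()


def csi_values(
    intensity: np.ndarray,
    duration: np.ndarray,
    time_since_cessation: np.ndarray,
    params: CsiParameters = DEFAULT_CSI_PARAMS,
) -> np.ndarray:
    """Vectorised CSI on raw exposure arrays.

    ``time_since_cessation`` must already be 0 for current smokers.  When
    ``params.sensitivity_lag`` is L > 0, exposure accrued in the last L
    years is removed before scoring: duration loses ``max(0, L - tsc)``
    years and cessation is treated as occurring ``max(tsc, L)`` years
    before the index date; histories whose truncated duration no longer
    exceeds one year score 0 (treated as never smokers).
    """
    i = np.asarray(intensity, dtype=float)
    d = np.asarray(duration, dtype=float)
    t = np.asarray(time_since_cessation, dtype=float)
    if np.any(i < 0) or np.any(d < 0) or np.any(t < 0):
        raise ValueError("intensity, duration and time_since_cessation must be >= 0")
    L = params.sensitivity_lag
    if L > 0:
        d = d - np.maximum(0.0, L - t)
        t = np.maximum(t, L)
        # truncation can demote short smokers to never
        never = d <= EVER_SMOKER_MIN_YEARS
        d = np.where(never, 0.0, d)
        i = np.where(never, 0.0, i)
        t = np.where(never, 0.0, t)
    tsc_star = np.maximum(t - params.delta, 0.0)
    dur_star = np.maximum(d + t - params.delta, 0.0) - tsc_star
    out = (1.0 - 0.5 ** (dur_star / params.tau)) * 0.5 ** (tsc_star / params.tau)
    return out * np.log1p(i)


def compute_csi(history: SmokingHistory, params: CsiParameters = DEFAULT_CSI_PARAMS) -> float:
    """Comprehensive smoking index for a single history.

    Current smokers are scored with time since cessation 0 (the half-year
    lag ``delta`` already discounts the most recent exposure).
    """
    tsc = 0.0 if history.status is SmokingStatus.CURRENT else history.time_since_cessation
    return float(
        csi_values(
            np.array([history.intensity]),
            np.array([history.duration]),
            np.array([tsc]),
            params,
        )[0]
    )


def compute_pack_years(history: SmokingHistory) -> float:
    """Pack-years: cigarettes per day x years smoked / 20."""
    return history.intensity * history.duration / 20.0


def pack_years_values(intensity: np.ndarray, duration: np.ndarray) -> np.ndarray:
    i = np.asarray(intensity, dtype=float)
    d = np.asarray(duration, dtype=float)
    if np.any(i < 0) or np.any(d < 0):
        raise ValueError("intensity and duration must be >= 0")
    return i * d / 20.0


def apply_sensitivity_lag(history: SmokingHistory, lag_years: float) -> SmokingHistory:
    """Smoking history as observed ``lag_years`` before the index date.

    Exposure accrued inside the discounted window is removed: duration
    loses ``max(0, lag - tsc)`` years and cessation is treated as occurring
    at ``max(tsc, lag)`` years before the original index date.  If the
    truncated duration no longer exceeds one year the participant counts
    as a never smoker for the lagged analysis.  ``lag_years = 0`` is the
    identity.
    """
    if lag_years < 0:
        raise ValueError("lag_years must be >= 0")
    if lag_years == 0 or history.status is SmokingStatus.NEVER:
        return history
    tsc0 = 0.0 if history.status is SmokingStatus.CURRENT else history.time_since_cessation
    new_dur = history.duration - max(0.0, lag_years - tsc0)
    new_tsc = max(tsc0, lag_years)
    if new_dur <= EVER_SMOKER_MIN_YEARS:
        return SmokingHistory(SmokingStatus.NEVER)
    status = SmokingStatus.CURRENT if new_tsc < 1 else SmokingStatus.FORMER
    return SmokingHistory(
        status=status,
        intensity=history.intensity,
        duration=new_dur,
        time_since_cessation=new_tsc,
        start_age=history.start_age,
    )


# --------------------------------------------------------------------------
# Categorical codings

#: Fixed daily-intensity bins (cigarettes/day): 1-9, 10-19, >=20.
INTENSITY_BIN_EDGES = (10.0, 20.0)
INTENSITY_BIN_LABELS = ("1-9", "10-19", ">=20")

TERTILE_SCHEMES = ("duration_tertiles", "packyear_tertiles", "csi_tertiles")
NEVER_LABEL = "never"


@dataclass(frozen=True)
class ExposureCoding:
    """A categorical coding of a smoking-exposure variable.

    Never smokers always map to the reference category ``"never"``; ever
    smokers map to exactly one non-reference category.  For tertile
    schemes the cutpoints are the empirical 1/3 and 2/3 quantiles of the
    variable among ever smokers and intervals are half-open ``(a, b]``
    (values equal to a cutpoint fall in the lower tertile).  For the fixed
    intensity bins the lower bound is inclusive (19 cig/day is "10-19",
    20 is ">=20").  ``category_medians`` hold the per-category median of
    the underlying continuous variable (0 for never smokers) and feed the
    median-score trend test.
    """

    scheme: str
    cutpoints: tuple
    labels: tuple
    category_medians: dict = field(default_factory=dict)

    @property
    def reference(self) -> str:
        return self.labels[0]

    def assign(self, values: Sequence, ever_flags: Sequence[bool]) -> pd.Categorical:
        """Map each participant to exactly one category label."""
        ever = np.asarray(ever_flags, dtype=bool)
        out = np.full(ever.shape, NEVER_LABEL, dtype=object)
        if self.scheme == "status":
            vals = np.asarray(values, dtype=object)
            out[ever] = [SmokingStatus(v).value for v in vals[ever]]
        else:
            vals = np.asarray(values, dtype=float)
            if self.scheme == "intensity_bins":
                idx = np.zeros(ever.shape, dtype=int)
                for c in self.cutpoints:
                    idx += (vals >= c).astype(int)
            else:
                idx = np.zeros(ever.shape, dtype=int)
                for c in self.cutpoints:
                    idx += (vals > c).astype(int)
            nonref = np.asarray(self.labels[1:], dtype=object)
            out[ever] = nonref[idx[ever]]
        return pd.Categorical(out, categories=list(self.labels), ordered=True)

    def median_scores(self, values: Sequence, ever_flags: Sequence[bool]) -> np.ndarray:
        """Each participant's category median (continuous trend score)."""
        if not self.category_medians:
            raise ValueError(f"scheme {self.scheme!r} has no category medians")
        cats = self.assign(values, ever_flags)
        return np.asarray([self.category_medians[c] for c in cats], dtype=float)


def make_coding(values: Sequence, ever_flags: Sequence[bool], scheme: str) -> ExposureCoding:
    """Build an :class:`ExposureCoding` from observed exposure values.

    ``values`` is the continuous variable for numeric schemes (daily
    intensity, duration, pack-years or CSI) or the status per participant
    for ``scheme="status"``.  Tertile cutpoints are linear-interpolation
    empirical quantiles among ever smokers.
    """
    ever = np.asarray(ever_flags, dtype=bool)
    if scheme == "status":
        coding = ExposureCoding(
            scheme="status",
            cutpoints=(),
            labels=(NEVER_LABEL, SmokingStatus.FORMER.value, SmokingStatus.CURRENT.value),
        )
        return coding
    vals = np.asarray(values, dtype=float)
    if scheme == "intensity_bins":
        cutpoints = INTENSITY_BIN_EDGES
        labels = (NEVER_LABEL,) + INTENSITY_BIN_LABELS
    elif scheme in TERTILE_SCHEMES:
        if ever.sum() < 3:
            raise ValueError(
                f"tertile coding requires at least 3 ever smokers, got {int(ever.sum())}"
            )
        q1, q2 = np.quantile(vals[ever], [1 / 3, 2 / 3], method="linear")
        cutpoints = (float(q1), float(q2))
        labels = (NEVER_LABEL, "tertile_1", "tertile_2", "tertile_3")
    else:
        raise ValueError(f"unknown coding scheme {scheme!r}")

    coding = ExposureCoding(scheme=scheme, cutpoints=cutpoints, labels=labels)
    cats = coding.assign(vals, ever)
    medians = {NEVER_LABEL: 0.0}
    for lab in labels[1:]:
        in_cat = np.asarray(cats == lab)
        medians[lab] = float(np.median(vals[in_cat])) if in_cat.any() else np.nan
    return replace(coding, category_medians=medians)
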