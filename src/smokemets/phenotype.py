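"""Metabolic-syndrome (MetS) component flagging and classification.

MetS is diagnosed when at least ``required_count`` (default 3) of five
cardiometabolic criteria are met: abdominal obesity (sex-specific waist
cut), elevated fasting plasma glucose (or glucose-lowering medication),
elevated blood pressure (systolic, diastolic, or antihypertensive
medication), elevated triglycerides, and low HDL cholesterol.  The shipped
preset ``CDS2013`` encodes the Chinese Diabetes Society 2013 thresholds;
alternative criteria sets (e.g. the 2009 Joint Interim Statement) can be
supplied as :class:`CriteriaSet` instances.

Missing measurements make individual component flags *missing* rather than
negative, and the classifier reports an explicit ``indeterminate`` status
whenever the observed flags do not decide the diagnosis: a participant is
positive iff enough flags are already positive, negative iff no completion
of the missing flags could reach the threshold, and indeterminate
otherwise (equivalently, determinate iff all completions of the missing
flags agree).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Flag",
    "MetsStatus",
    "MetsProfile",
    "CriteriaSet",
    "MetsCall",
    "CDS2013",
    "COMPONENTS",
    "flag_components",
    "classify_mets",
    "flag_components_frame",
    "classify_frame",
]

COMPONENTS = ("obesity", "glucose", "blood_pressure", "triglycerides", "hdl")


class Flag(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"


class MetsStatus(str, Enum):
    POSITIVE = "mets_positive"
    NEGATIVE = "mets_negative"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MetsProfile:
    """Five component measurements, medication flags and sex for one person.

    Any measurement may be ``None`` (missing); present measurements must be
    strictly positive and systolic pressure must exceed diastolic.
    """

    sex: str  # "male" | "female"
    waist: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    fpg: Optional[float] = None
    tg: Optional[float] = None
    hdl: Optional[float] = None
    on_glucose_meds: Optional[bool] = False
    on_bp_meds: Optional[bool] = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("waist", "sbp", "dbp", "fpg", "tg", "hdl"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.sbp is not None and self.dbp is not None and not self.sbp > self.dbp:
            raise ValueError("systolic pressure must exceed diastolic")


@dataclass(frozen=True)
class CriteriaSet:
    """Thresholds defining the five MetS components and the vote count."""

    name: str
    waist_cut_male: float
    waist_cut_female: float
    fpg_cut: float
    sbp_cut: float
    dbp_cut: float
    tg_cut: float
    hdl_cut: float
    required_count: int = 3

    def __post_init__(self) -> None:
        cuts = (
            self.waist_cut_male, self.waist_cut_female, self.fpg_cut,
            self.sbp_cut, self.dbp_cut, self.tg_cut, self.hdl_cut,
        )
        if any(c <= 0 for c in cuts):
            raise ValueError("all thresholds must be positive")
        if not 1 <= self.required_count <= 5:
            raise ValueError("required_count must be between 1 and 5")


#: Chinese Diabetes Society 2013 definition: waist >=90 cm (men) / >=85 cm
#: (women); FPG >=6.1 mmol/L or glucose medication; BP >=130/85 mmHg or
#: antihypertensive medication; TG >=1.7 mmol/L; HDL <1.04 mmol/L; >=3 of 5.
CDS2013 = CriteriaSet(
    name="CDS2013",
    waist_cut_male=90.0,
    waist_cut_female=85.0,
    fpg_cut=6.1,
    sbp_cut=130.0,
    dbp_cut=85.0,
    tg_cut=1.7,
    hdl_cut=1.04,
    required_count=3,
)

CRITERIA_PRESETS = {"CDS2013": CDS2013}


@dataclass(frozen=True)
class MetsCall:
    component_flags: tuple  # five Flag values, ordered as COMPONENTS
    status: MetsStatus
    n_positive: int
    n_negative: int
    n_missing: int


def _threshold_flag(value: Optional[float], cut: float, *, low: bool = False) -> Flag:
    if value is None:
        return Flag.MISSING
    hit = value < cut if low else value >= cut
    return Flag.POSITIVE if hit else Flag.NEGATIVE


def flag_components(profile: MetsProfile, criteria: CriteriaSet = CDS2013) -> tuple:
    """Tri-state flags for the five components, ordered as ``COMPONENTS``.

    A flag is missing only when every datum that could decide it is
    missing; e.g. the glucose flag is positive with missing FPG when the
    participant reports glucose-lowering medication.
    """
    waist_cut = criteria.waist_cut_male if profile.sex == "male" else criteria.waist_cut_female
    obesity = _threshold_flag(profile.waist, waist_cut)

    if profile.on_glucose_meds:
        glucose = Flag.POSITIVE
    else:
        glucose = _threshold_flag(profile.fpg, criteria.fpg_cut)

    if profile.on_bp_meds:
        bp = Flag.POSITIVE
    elif (profile.sbp is not None and profile.sbp >= criteria.sbp_cut) or (
        profile.dbp is not None and profile.dbp >= criteria.dbp_cut
    ):
        bp = Flag.POSITIVE
    elif profile.sbp is None and profile.dbp is None:
        bp = Flag.MISSING
    elif profile.sbp is None or profile.dbp is None:
        # one pressure observed and below its cut: the unseen one could
        # still exceed its cut, so the flag is undecided
        bp = Flag.MISSING
    else:
        bp = Flag.NEGATIVE

    tg = _threshold_flag(profile.tg, criteria.tg_cut)
    hdl = _threshold_flag(profile.hdl, criteria.hdl_cut, low=True)
    return (obesity, glucose, bp, tg, hdl)


def classify_mets(flags: Sequence[Flag], required_count: int = 3) -> MetsCall:
    """Classify MetS from five tri-state flags.

    Positive iff enough flags are already positive; negative iff even
    counting every missing flag as positive cannot reach the threshold;
    indeterminate otherwise.  This matches enumeration of all completions
    of the missing flags: the status is determinate iff they all agree.
    """
    flags = tuple(Flag(f) for f in flags)
    if len(flags) != 5:
        raise ValueError(f"expected exactly 5 flags, got {len(flags)}")
    n_pos = sum(f is Flag.POSITIVE for f in flags)
    n_neg = sum(f is Flag.NEGATIVE for f in flags)
    n_mis = 5 - n_pos - n_neg
    if n_pos >= required_count:
        status = MetsStatus.POSITIVE
    elif n_pos + n_mis < required_count:
        status = MetsStatus.NEGATIVE
    else:
        status = MetsStatus.INDETERMINATE
    return MetsCall(flags, status, n_pos, n_neg, n_mis)


def classify_by_enumeration(flags: Sequence[Flag], required_count: int = 3) -> MetsStatus:
    """Reference classifier: enumerate all completions of missing flags."""
    flags = tuple(Flag(f) for f in flags)
    missing_idx = [i for i, f in enumerate(flags) if f is Flag.MISSING]
    outcomes = set()
    for fill in itertools.product([Flag.POSITIVE, Flag.NEGATIVE], repeat=len(missing_idx)):
        completed = list(flags)
        for i, f in zip(missing_idx, fill):
            completed[i] = f
        n_pos = sum(f is Flag.POSITIVE for f in completed)
        outcomes.add(n_pos >= required_count)
    if outcomes == {True}:
        return MetsStatus.POSITIVE
    if outcomes == {False}:
        return MetsStatus.NEGATIVE
    return MetsStatus.INDETERMINATE


# --------------------------------------------------------------------------
# Vectorised frame interface

def flag_components_frame(df: pd.DataFrame, criteria: CriteriaSet = CDS2013) -> pd.DataFrame:
    """Component flags for a participant table.

    Expects columns ``sex, waist, sbp, dbp, fpg, tg, hdl, on_glucose_meds,
    on_bp_meds`` (measurements may be NaN; med flags NaN counts as False).
    Returns a frame of columns ``flag_<component>`` coded 1 (positive),
    0 (negative), NaN (missing).
    """
    male = df["sex"].to_numpy() == "male"
    waist = df["waist"].to_numpy(dtype=float)
    sbp = df["sbp"].to_numpy(dtype=float)
    dbp = df["dbp"].to_numpy(dtype=float)
    fpg = df["fpg"].to_numpy(dtype=float)
    tg = df["tg"].to_numpy(dtype=float)
    hdl = df["hdl"].to_numpy(dtype=float)
    gmeds = df["on_glucose_meds"].fillna(False).to_numpy(dtype=bool)
    bmeds = df["on_bp_meds"].fillna(False).to_numpy(dtype=bool)

    def tri(pos: np.ndarray, missing: np.ndarray) -> np.ndarray:
        out = pos.astype(float)
        out[missing] = np.nan
        return out

    waist_cut = np.where(male, criteria.waist_cut_male, criteria.waist_cut_female)
    obesity = tri(waist >= waist_cut, np.isnan(waist))
    glucose = tri((fpg >= criteria.fpg_cut) | gmeds, np.isnan(fpg) & ~gmeds)
    bp_pos = (sbp >= criteria.sbp_cut) | (dbp >= criteria.dbp_cut) | bmeds
    # undecided unless medicated, some pressure exceeds its cut, or both
    # pressures are observed below their cuts
    bp_missing = ~bp_pos & (np.isnan(sbp) | np.isnan(dbp))
    bp = tri(bp_pos, bp_missing)
    tg_f = tri(tg >= criteria.tg_cut, np.isnan(tg))
    hdl_f = tri(hdl < criteria.hdl_cut, np.isnan(hdl))

    return pd.DataFrame(
        {
            "flag_obesity": obesity,
            "flag_glucose": glucose,
            "flag_blood_pressure": bp,
            "flag_triglycerides": tg_f,
            "flag_hdl": hdl_f,
        },
        index=df.index,
    )


def classify_frame(flags: pd.DataFrame, required_count: int = 3) -> pd.Series:
    """Vectorised MetS status for a frame of 1/0/NaN component flags."""
    cols = [c for c in flags.columns if c.startswith("flag_")]
    if len(cols) != 5:
        raise ValueError(f"expected 5 flag columns, found {len(cols)}")
    arr = flags[cols].to_numpy(dtype=float)
    n_pos = np.nansum(arr == 1, axis=1)
    n_mis = np.isnan(arr).sum(axis=1)
    status = np.where(
        n_pos >= required_count,
        MetsStatus.POSITIVE.value,
        np.where(
            n_pos + n_mis < required_count,
            MetsStatus.NEGATIVE.value,
            MetsStatus.INDETERMINATE.value,
        ),
    )
    return pd.Series(status, index=flags.index, name="mets_status")
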