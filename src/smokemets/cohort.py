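"""Synthetic participant cohorts with known ground truth.

The generator emulates the structure of two cross-sectional Chinese
survey samples — an urban cohort of older adults (``discovery_like``,
ages >= 60) and a nationwide multi-province adult sample
(``replication_like``, ages >= 18) — closely enough that every pipeline
stage (exposure scoring, MetS classification, adjusted models,
interaction and imputation analyses) can be exercised with a known
data-generating process.

Smoking histories are drawn with sex-differential initiation, a start
age, a discretised log-normal daily intensity clipped to [1, 60]
cigarettes, and a quit process guaranteeing that former smokers ceased
at least one year before the index date and every ever smoker smoked for
more than one year.  The five MetS component *criteria* are drawn from
per-component logistic models on age, sex, BMI and the participant's true
comprehensive smoking index (CSI), plus one shared standard-normal latent
factor that induces component clustering.  Smoking acts on components
(strongest on blood pressure and HDL), not on MetS directly, so the
MetS-level odds ratio is an emergent quantity; measure it by simulating a
very large cohort with the same parameters (a self-oracle).  The smoking
effect is multiplied by ``age_modification`` below age 70.

A global intercept shift shared by all five components is calibrated by
root-finding against the simulator itself so that the expected
>=3-component co-occurrence rate equals ``target_mets_prevalence``; the
exact Poisson-binomial tail probability is used, making the calibration
smooth and deterministic.

Measurements (waist, blood pressures, fasting glucose, triglycerides,
HDL) and medication flags are then materialised consistently with the
drawn criterion flags.  Optionally, a requested number of records is made
*equivocal* (component data masked until neither MetS presence nor
absence is decidable) and a requested number loses a crucial covariate,
for eligibility-filter testing.  ``inject_missingness`` masks covariate
and smoking fields completely at random or with an age/sex-tilted
(missing-at-random) mechanism at a configurable record-level rate.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import yaml

from .exposure import csi_values, pack_years_values
from .phenotype import COMPONENTS

__all__ = [
    "TrueEffects",
    "CohortSpec",
    "generate_cohort",
    "inject_missingness",
    "calibrated_shift",
    "mets_probability",
]

# internal deterministic stream for intercept calibration; independent of
# the cohort seed so that cohorts differing only by seed share intercepts
_CALIBRATION_SEED = 191817
_CALIBRATION_N = 200_000


@dataclass(frozen=True)
class TrueEffects:
    """Per-component log-odds effects, ordered as ``phenotype.COMPONENTS``
    (obesity, glucose, blood_pressure, triglycerides, hdl)."""

    csi: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)        # per CSI unit (ages >= 70)
    age_per10: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)  # per decade of age
    male: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    bmi: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)        # per kg/m^2 (centred)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of one synthetic cohort."""

    n: int
    seed: int
    profile: str = "discovery_like"
    # demographics
    sex_male_frac: float = 0.465
    age_min: float = 60.0
    age_gamma_shape: float = 1.6   # age = age_min + Gamma(shape, scale)
    age_gamma_scale: float = 5.7
    age_center: float = 69.0
    bmi_mean: float = 24.2
    bmi_sd: float = 2.9
    # smoking
    ever_prev_male: float = 0.20
    ever_prev_female: float = 0.011
    current_frac: float = 0.94
    intensity_log_mu: float = float(np.log(15.0))
    intensity_log_sigma: float = 0.55
    intensity_age_per10: float = 0.0   # log-intensity change per decade of age
    start_age_mean: float = 21.0
    start_age_sd: float = 4.0
    tsc_gamma_shape: float = 1.5
    tsc_gamma_scale: float = 6.0
    # lifestyle covariates: name -> {level: probability}
    covariates: dict = field(default_factory=dict)
    # outcome model
    true_effects: TrueEffects = field(default_factory=TrueEffects)
    age_modification: float = 1.0   # multiplier on the CSI effect below 70 y
    component_correlation: float = 0.9  # latent-factor loading
    component_base_rates: tuple = (0.23, 0.33, 0.43, 0.33, 0.28)
    target_mets_prevalence: float = 0.233
    # medication behaviour among criterion-positive participants
    bp_meds_frac: float = 0.35
    bp_controlled_frac: float = 0.4
    glucose_meds_frac: float = 0.30
    glucose_controlled_frac: float = 0.35
    # data-quality knobs
    missingness_rate: float = 0.071
    equivocal_count: int = 0
    ineligible_covariate_count: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be > 0")
        for name in ("sex_male_frac", "ever_prev_male", "ever_prev_female",
                     "current_frac", "target_mets_prevalence", "missingness_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.component_base_rates) != 5:
            raise ValueError("component_base_rates must have 5 entries")

    @classmethod
    def from_profile(cls, profile: str, n: int, seed: int, **overrides) -> "CohortSpec":
        """Load a shipped parameter file (``discovery_like`` or
        ``replication_like``) and apply overrides."""
        ref = resources.files("smokemets") / "profiles" / f"{profile}.cfg"
        params = yaml.safe_load(ref.read_text())
        params["true_effects"] = TrueEffects(
            **{k: tuple(v) for k, v in params.get("true_effects", {}).items()}
        )
        params["component_base_rates"] = tuple(params["component_base_rates"])
        params.update(overrides)
        return cls(n=n, seed=seed, profile=profile, **params)


def _freeze(obj):
    if isinstance(obj, dict):
        return tuple(sorted((k, _freeze(v)) for k, v in obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(_freeze(v) for v in obj)
    return obj


def _linear_predictors(spec: CohortSpec, rng: np.random.Generator, n: int) -> dict:
    """Draw everything upstream of the component intercepts."""
    male = rng.random(n) < spec.sex_male_frac
    age = spec.age_min + rng.gamma(spec.age_gamma_shape, spec.age_gamma_scale, n)
    age = np.minimum(age, 99.0)
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 15.0, 45.0)

    prev = np.where(male, spec.ever_prev_male, spec.ever_prev_female)
    ever = rng.random(n) < prev
    current = ever & (rng.random(n) < spec.current_frac)

    start_age = np.clip(rng.normal(spec.start_age_mean, spec.start_age_sd, n), 12.0, age - 3.0)
    tsc = np.zeros(n)
    former = ever & ~current
    tsc_draw = 1.0 + rng.gamma(spec.tsc_gamma_shape, spec.tsc_gamma_scale, n)
    tsc[former] = np.minimum(tsc_draw, age - start_age - 1.5)[former]
    duration = np.where(ever, age - start_age - tsc, 0.0)
    log_mu = spec.intensity_log_mu + spec.intensity_age_per10 * (age - spec.age_center) / 10.0
    intensity = np.where(
        ever,
        np.clip(np.round(np.exp(rng.normal(log_mu, spec.intensity_log_sigma))), 1, 60),
        0.0,
    )
    start_age = np.where(ever, start_age, np.nan)
    tsc = np.where(ever, tsc, 0.0)

    csi = csi_values(intensity, duration, tsc)
    z = rng.standard_normal(n)

    eff = spec.true_effects
    young = age < 70.0
    eta = np.empty((n, 5))
    for j in range(5):
        csi_slope = eff.csi[j] * np.where(young, spec.age_modification, 1.0)
        eta[:, j] = (
            scipy.special.logit(spec.component_base_rates[j])
            + eff.age_per10[j] * (age - spec.age_center) / 10.0
            + eff.male[j] * male
            + eff.bmi[j] * (bmi - spec.bmi_mean)
            + csi_slope * csi
            + spec.component_correlation * z
        )
    return dict(
        male=male, age=age, bmi=bmi, ever=ever, current=current, former=former,
        start_age=start_age, tsc=tsc, duration=duration, intensity=intensity,
        csi=csi, z=z, eta=eta,
    )


def mets_probability(eta: np.ndarray, shift: float, required: int = 3) -> np.ndarray:
    """Exact P(>= required components positive) per participant, given the
    five per-component logits (Poisson-binomial tail)."""
    p = scipy.special.expit(eta + shift)
    counts = np.zeros((p.shape[0], 6))
    counts[:, 0] = 1.0
    for j in range(5):
        pj = p[:, j][:, None]
        shifted = np.zeros_like(counts)
        shifted[:, 1:] = counts[:, :-1]
        counts = counts * (1 - pj) + shifted * pj
    return counts[:, required:].sum(axis=1)


def _shift_key(spec: CohortSpec) -> tuple:
    s = replace(spec, n=1, seed=0, equivocal_count=0, ineligible_covariate_count=0)
    return _freeze(
        {k: getattr(s, k) for k in s.__dataclass_fields__ if k not in ("covariates",)}
    ) + (_freeze(spec.covariates),)


@functools.lru_cache(maxsize=64)
def _calibrated_shift_cached(key: tuple, spec_bytes: bytes) -> float:
    import pickle

    spec: CohortSpec = pickle.loads(spec_bytes)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    eta = _linear_predictors(spec, rng, _CALIBRATION_N)["eta"]

    def gap(s: float) -> float:
        return float(mets_probability(eta, s).mean()) - spec.target_mets_prevalence

    lo, hi = -15.0, 15.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"target MetS prevalence {spec.target_mets_prevalence} unreachable "
            "under the specified effects (intercept calibration failed)"
        )
    return float(scipy.optimize.brentq(gap, lo, hi, xtol=1e-6))


def calibrated_shift(spec: CohortSpec) -> float:
    """Global component-intercept shift matching the MetS prevalence target.

    Deterministic given the spec's model parameters (independent of ``n``
    and ``seed``), so cohorts replicated with different seeds share the
    same data-generating process.
    """
    import pickle

    key = _shift_key(spec)
    norm = replace(spec, n=1, seed=0, equivocal_count=0, ineligible_covariate_count=0)
    return _calibrated_shift_cached(key, pickle.dumps(norm))


def _materialise_measurements(
    flags: np.ndarray, male: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> dict:
    """Component measurements and medication flags consistent with the
    drawn criterion flags (flag order as ``phenotype.COMPONENTS``)."""
    n = flags.shape[0]
    obesity, glucose, bp, tg, hdl = (flags[:, j].astype(bool) for j in range(5))

    waist_cut = np.where(male, 90.0, 85.0)
    waist = np.where(
        obesity,
        waist_cut + rng.gamma(2.0, 3.0, n),
        np.maximum(waist_cut - 0.5 - rng.gamma(2.0, 4.0, n), 55.0),
    )

    on_bp_meds = bp & (rng.random(n) < spec.bp_meds_frac)
    bp_controlled = on_bp_meds & (rng.random(n) < spec.bp_controlled_frac)
    sbp = np.where(
        bp & ~bp_controlled,
        130.0 + rng.gamma(2.0, 7.0, n),
        100.0 + rng.random(n) * 29.5,
    )
    dbp = np.clip(sbp - (15.0 + rng.random(n) * 30.0), 50.0, None)
    dbp = np.where(bp & ~bp_controlled, dbp, np.minimum(dbp, 84.5))
    sbp = np.maximum(sbp, dbp + 5.0)

    on_glucose_meds = glucose & (rng.random(n) < spec.glucose_meds_frac)
    glu_controlled = on_glucose_meds & (rng.random(n) < spec.glucose_controlled_frac)
    fpg = np.where(
        glucose & ~glu_controlled,
        6.1 + rng.gamma(1.5, 1.2, n),
        4.0 + rng.random(n) * 2.0,
    )

    tg_v = np.where(tg, 1.7 + rng.gamma(1.5, 0.9, n), 0.5 + rng.random(n) * 1.15)
    hdl_v = np.where(
        hdl,
        np.maximum(1.02 - rng.random(n) * 0.45, 0.35),
        1.045 + rng.gamma(1.5, 0.25, n),
    )
    return dict(
        waist=waist, sbp=sbp, dbp=dbp, fpg=fpg, tg=tg_v, hdl=hdl_v,
        on_bp_meds=on_bp_meds, on_glucose_meds=on_glucose_meds,
    )


_COMPONENT_FIELDS = {
    "obesity": ("waist",),
    "glucose": ("fpg",),
    "blood_pressure": ("sbp", "dbp"),
    "triglycerides": ("tg",),
    "hdl": ("hdl",),
}


def _make_equivocal(df: pd.DataFrame, idx: np.ndarray, rng: np.random.Generator) -> None:
    """Mask component measurements of the chosen rows until MetS status is
    indeterminate (in place).

    Masking a component turns its flag from positive/negative to missing;
    a row is indeterminate once fewer than 3 flags are observed positive
    while the missing flags could still reach 3.  Components decided by a
    medication flag cannot be masked (the medication response is kept),
    which still always leaves enough maskable components to reach an
    indeterminate state.
    """
    from .phenotype import flag_components_frame

    sub = df.loc[idx]
    flags = flag_components_frame(sub).to_numpy()  # (k, 5) of 1/0
    gmeds = sub["on_glucose_meds"].to_numpy(dtype=bool)
    bmeds = sub["on_bp_meds"].to_numpy(dtype=bool)
    to_mask: dict = {c: [] for c in COMPONENTS}
    for r, i in enumerate(idx):
        maskable = [
            j for j, c in enumerate(COMPONENTS)
            if not (c == "glucose" and gmeds[r]) and not (c == "blood_pressure" and bmeds[r])
        ]
        rng.shuffle(maskable)
        n_pos = int(flags[r].sum())
        n_mis = 0
        for j in maskable:
            n_pos -= int(flags[r, j])
            n_mis += 1
            to_mask[COMPONENTS[j]].append(i)
            if n_pos < 3 and n_pos + n_mis >= 3:
                break
    for comp, rows in to_mask.items():
        if rows:
            for fld in _COMPONENT_FIELDS[comp]:
                df.loc[rows, fld] = np.nan


def generate_cohort(spec: CohortSpec, shift: Optional[float] = None) -> tuple:
    """Draw a cohort; returns ``(frame, truth)``.

    ``truth`` is the ground-truth ledger: the spec, the calibrated
    intercept shift, the per-participant true CSI and the drawn component
    flags.  Pass ``shift`` to reuse a calibration (or probe the model at
    fixed intercepts).
    """
    rng = np.random.default_rng(spec.seed)
    draw = _linear_predictors(spec, rng, spec.n)
    if shift is None:
        shift = calibrated_shift(spec)
    p = scipy.special.expit(draw["eta"] + shift)
    flags = (rng.random((spec.n, 5)) < p).astype(int)

    meas = _materialise_measurements(flags, draw["male"], spec, rng)

    status = np.where(draw["current"], "current", np.where(draw["former"], "former", "never"))
    df = pd.DataFrame(
        {
            "id": np.arange(spec.n),
            "age": draw["age"],
            "sex": np.where(draw["male"], "male", "female"),
            "bmi": draw["bmi"],
            "smoking_status": status,
            "intensity": draw["intensity"],
            "duration": draw["duration"],
            "time_since_cessation": draw["tsc"],
            "start_age": draw["start_age"],
            **meas,
        }
    )
    for name, levels in (spec.covariates or {}).items():
        labs = list(levels)
        probs = np.array([levels[k] for k in labs], dtype=float)
        df[name] = rng.choice(labs, size=spec.n, p=probs / probs.sum())

    if spec.equivocal_count or spec.ineligible_covariate_count:
        chosen = rng.choice(spec.n, spec.equivocal_count + spec.ineligible_covariate_count,
                            replace=False)
        equiv_idx = chosen[: spec.equivocal_count]
        inel_idx = chosen[spec.equivocal_count:]
        _make_equivocal(df, equiv_idx, rng)
        if len(inel_idx):
            if spec.profile == "replication_like":
                df.loc[inel_idx, "smoking_status"] = np.nan
            else:
                crucial = "diet" if "diet" in df.columns else "age"
                df.loc[inel_idx, crucial] = np.nan

    truth = dict(
        spec=spec,
        shift=float(shift),
        csi=draw["csi"],
        pack_years=pack_years_values(draw["intensity"], draw["duration"]),
        component_flags=flags,
        latent=draw["z"],
        mets_true=(flags.sum(axis=1) >= 3).astype(int),
    )
    return df, truth


def inject_missingness(
    df: pd.DataFrame,
    rate: float = 0.071,
    mechanism: str = "MAR",
    fields: Sequence[str] = ("bmi", "intensity"),
    seed: int = 0,
) -> tuple:
    """Mask the given fields for a random subset of records.

    ``mechanism="MCAR"`` selects records uniformly; ``"MAR"`` ties the
    selection probability to observed age and sex through a logistic link
    (older participants and men are more likely to be masked; the
    intercept is solved so the expected rate equals ``rate``).  Smoking
    fields are only masked for ever smokers.  Returns
    ``(masked_frame, selected_mask)``.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(df)
    if rate == 0:
        return df.copy(), np.zeros(n, dtype=bool)
    if mechanism == "MCAR":
        lin = np.zeros(n)
    elif mechanism == "MAR":
        # elderly underreporting: masking rises with age and is slightly
        # more common in men
        age = df["age"].to_numpy(dtype=float)
        male = (df["sex"].to_numpy() == "male").astype(float)
        lin = 1.2 * (age - age.mean()) / age.std() + 0.3 * male
    elif mechanism == "MAR_outcome":
        # exam-item avoidance concentrated in affected smokers: masking
        # depends on the observed smoking status and MetS outcome jointly
        if "mets" in df.columns:
            mets = df["mets"].to_numpy(dtype=float)
        else:
            from .phenotype import CDS2013
            from .pipeline import add_phenotype

            mets = add_phenotype(df, CDS2013)["mets"].to_numpy(dtype=float)
        ever = df["smoking_status"].isin(["former", "current"]).to_numpy(dtype=float)
        lin = 0.8 * ever + 0.8 * mets + 1.2 * ever * mets
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    def gap(a: float) -> float:
        return float(scipy.special.expit(a + lin).mean()) - rate

    a0 = scipy.optimize.brentq(gap, -25, 15)
    prob = scipy.special.expit(a0 + lin)
    selected = rng.random(n) < prob
    out = df.copy()
    smoking_fields = {"intensity", "duration", "time_since_cessation", "start_age"}
    ever = df["smoking_status"].isin(["former", "current"]).to_numpy()
    for f in fields:
        target = selected & ever if f in smoking_fields else selected
        out.loc[target, f] = np.nan
    return out, selected
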