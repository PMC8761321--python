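"""End-to-end discovery/replication study workflow.

Stages: eligibility filtering (indeterminate MetS first, then missing
crucial covariates or invalid smoking response, each exclusion counted
once under the first applicable reason), optional missing-data handling
(median replacement or chained-equation multiple imputation), exposure
scoring and coding, MetS phenotyping, and the four report tables —
group descriptives, adjusted ORs per smoking variable, per-component
associations, and interaction/RERI rows — plus the configured
sensitivity reruns (3-year exposure discount; common covariate set).
All artefacts are plain delimited text with a JSON run manifest; a rerun
with the same configuration and seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationTable,
    category_association,
    descriptive_table,
    stepwise_select,
)
from .cohort import CohortSpec, generate_cohort
from .exposure import CsiParameters, csi_values, make_coding, pack_years_values
from .imputation import ImputationSpec, chained_impute, median_replace, pool_rubin
from .interaction import interaction_analysis
from .phenotype import CRITERIA_PRESETS, CriteriaSet, MetsStatus, classify_frame, flag_components_frame

__all__ = [
    "StudyConfig",
    "StudyResult",
    "add_exposure",
    "add_phenotype",
    "add_modifiers",
    "filter_eligible",
    "run_study",
    "DEFAULT_SCHEMES",
    "SCHEME_VALUE_COLUMNS",
]

DEFAULT_SCHEMES = (
    "status",
    "intensity_bins",
    "duration_tertiles",
    "packyear_tertiles",
    "csi_tertiles",
)

SCHEME_VALUE_COLUMNS = {
    "status": "smoking_status",
    "intensity_bins": "intensity",
    "duration_tertiles": "duration",
    "packyear_tertiles": "pack_years",
    "csi_tertiles": "csi",
}

#: covariate sets mirroring the two cohort protocols; the "common" set is
#: the shared sensitivity adjustment (sex, age, BMI)
PROFILE_COVARIATES = {
    "discovery_like": ("age", "exercise", "bmi", "diet"),
    "replication_like": ("sex", "age", "bmi", "province", "region"),
}
COMMON_COVARIATES = ("sex", "age", "bmi")

MODIFIER_COLUMNS = ("mod_age_lt70", "mod_male", "mod_exercise_like", "mod_alcohol_ever")

#: covariates that deterministically encode each modifier dichotomy
MODIFIER_SOURCE = {
    "mod_male": ("sex",),
    "mod_exercise_like": ("exercise", "sports_like"),
    "mod_alcohol_ever": ("alcohol",),
    "mod_age_lt70": (),
}


@dataclass
class StudyConfig:
    profile: str = "discovery_like"
    input_path: Optional[str] = None   # delimited text; None -> synthesise
    n: int = 15222
    seed: int = 0
    criteria: str = "CDS2013"
    schemes: tuple = DEFAULT_SCHEMES
    covariate_policy: str = "fixed"    # fixed | stepwise | common
    covariates: Optional[tuple] = None  # overrides the profile preset
    stepwise_candidates: Optional[tuple] = None
    modifiers: tuple = MODIFIER_COLUMNS
    impute: str = "median"             # median | mice | none
    imputation_m: int = 5
    imputation_iterations: int = 10
    lag_years: float = 0.0
    sensitivity_lag3: bool = True
    sensitivity_common_covariates: bool = True
    bonferroni: bool = False   # adjust trend p-values across smoking variables
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("schemes", "covariates", "stepwise_candidates", "modifiers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _criteria(config_or_name) -> CriteriaSet:
    if isinstance(config_or_name, CriteriaSet):
        return config_or_name
    try:
        return CRITERIA_PRESETS[config_or_name]
    except KeyError:
        raise ValueError(
            f"unknown criteria preset {config_or_name!r}; available: {sorted(CRITERIA_PRESETS)}"
        ) from None


def add_exposure(
    df: pd.DataFrame,
    params: CsiParameters = CsiParameters(),
    intensity_median_replace: bool = True,
) -> pd.DataFrame:
    """Append ``csi``, ``pack_years`` and ``ever_smoker`` columns.

    Missing daily intensity among ever smokers is replaced by the
    ever-smoker median before scoring (the discovery-protocol rule);
    current smokers are scored with time since cessation 0.
    """
    out = df.copy()
    ever = out["smoking_status"].isin(["former", "current"]).to_numpy()
    intensity = out["intensity"].to_numpy(dtype=float)
    if intensity_median_replace and np.isnan(intensity[ever]).any():
        intensity = median_replace(intensity, ever)
        out["intensity"] = intensity
    duration = np.where(ever, out["duration"].to_numpy(dtype=float), 0.0)
    tsc = np.where(
        out["smoking_status"].to_numpy() == "current",
        0.0,
        np.where(ever, out["time_since_cessation"].to_numpy(dtype=float), 0.0),
    )
    intensity = np.where(ever, intensity, 0.0)
    lag = params.sensitivity_lag
    lagged_dur = duration - np.maximum(0.0, lag - tsc)
    demoted = ever & (lagged_dur <= 1.0) if lag > 0 else np.zeros_like(ever)
    out["csi"] = csi_values(intensity, duration, tsc, params)
    out["pack_years"] = np.where(
        demoted, 0.0, pack_years_values(intensity, np.maximum(lagged_dur, 0.0))
    )
    out["ever_smoker"] = ever & ~demoted
    return out


def add_phenotype(df: pd.DataFrame, criteria: CriteriaSet) -> pd.DataFrame:
    """Append the five component flags and the MetS status column."""
    out = df.copy()
    flags = flag_components_frame(out, criteria)
    out = pd.concat([out, flags], axis=1)
    out["mets_status"] = classify_frame(flags, criteria.required_count)
    out["mets"] = (out["mets_status"] == MetsStatus.POSITIVE.value).astype(int)
    return out


def add_modifiers(df: pd.DataFrame, profile: str) -> pd.DataFrame:
    """Binary effect-modifier columns: age < 70, sex, exercise, alcohol."""
    out = df.copy()
    out["mod_age_lt70"] = (out["age"] < 70).astype(int)
    out["mod_male"] = (out["sex"] == "male").astype(int)
    if profile == "replication_like" and "sports_like" in out.columns:
        like = out["sports_like"].isin(["neutral", "like_somewhat", "like_very_much"])
    elif "exercise" in out.columns:
        like = out["exercise"].isin(["often", "every_day"])
    else:
        like = pd.Series(False, index=out.index)
    out["mod_exercise_like"] = like.astype(int)
    if "alcohol" in out.columns:
        out["mod_alcohol_ever"] = (out["alcohol"] != "never").astype(int)
    else:
        out["mod_alcohol_ever"] = 0
    return out


CRUCIAL_COVARIATES = {"discovery_like": ("age", "diet"), "replication_like": ()}


def filter_eligible(df: pd.DataFrame, profile: str, criteria: CriteriaSet = None) -> tuple:
    """Apply the enrollment exclusions; returns ``(retained, tally)``.

    Reasons are applied in order and each excluded record is counted once
    under the first reason that applies: (1) indeterminate (equivocal)
    MetS status; (2) discovery profile: missing crucial covariates (age,
    dietary habits); replication profile: invalid or missing smoking
    response.  The tally always reconciles: input n = retained + sum of
    per-reason counts.
    """
    from .phenotype import CDS2013

    criteria = criteria or CDS2013
    work = df
    if "mets_status" not in work.columns:
        work = add_phenotype(work, criteria)
    n_input = len(work)
    tally: dict = {"input": n_input}

    equivocal = (work["mets_status"] == MetsStatus.INDETERMINATE.value).to_numpy()
    tally["equivocal_mets"] = int(equivocal.sum())
    remaining = ~equivocal

    if profile == "discovery_like":
        crucial = [c for c in CRUCIAL_COVARIATES[profile] if c in work.columns]
        bad = work[crucial].isna().any(axis=1).to_numpy() if crucial else np.zeros(n_input, bool)
        tally["missing_crucial_covariates"] = int((bad & remaining).sum())
        remaining &= ~bad
    else:
        valid = work["smoking_status"].isin(["never", "former", "current"]).to_numpy()
        tally["invalid_smoking_response"] = int((~valid & remaining).sum())
        remaining &= valid

    tally["retained"] = int(remaining.sum())
    return work.loc[remaining].reset_index(drop=True), tally


# --------------------------------------------------------------------------
# full study

@dataclass
class StudyResult:
    config: StudyConfig
    exclusions: dict
    covariates_used: tuple
    table1: pd.DataFrame
    table2: dict          # scheme -> AssociationTable
    table3: dict          # component -> AssociationTable
    table4: dict          # modifier -> InteractionResult
    sensitivity: dict = field(default_factory=dict)
    codings: dict = field(default_factory=dict)
    n_analysis: int = 0


def _association_frame(tables: dict) -> pd.DataFrame:
    rows = []
    for name, at in tables.items():
        t = at.table.copy()
        t.insert(0, "variable", name)
        t["trend_p"] = at.trend_p
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def _pool_tables(per_dataset: list) -> AssociationTable:
    """Rubin-pool the log-ORs of one scheme across imputed datasets."""
    first = per_dataset[0]
    pooled = first.table.copy()
    for i, row in pooled.iterrows():
        cat = row["category"]
        if cat == first.reference:
            continue
        term = f"exposure[{cat}]"
        est = [at.fit.params[term] for at in per_dataset]
        var = [float(at.fit.cov.loc[term, term]) for at in per_dataset]
        pe = pool_rubin(est, var)
        pooled.loc[i, "odds_ratio"] = float(np.exp(pe.estimate))
        pooled.loc[i, "ci_low"] = float(np.exp(pe.ci[0]))
        pooled.loc[i, "ci_high"] = float(np.exp(pe.ci[1]))
    trend = float(np.median([at.trend_p for at in per_dataset]))
    return AssociationTable(
        scheme=first.scheme,
        reference=first.reference,
        table=pooled,
        trend_p=trend,
        adjusted_for=first.adjusted_for,
        fit=None,
    )


def _mice_datasets(df: pd.DataFrame, config: StudyConfig) -> list:
    """Impute incomplete smoking dimensions and BMI, keeping the outcome
    and demographics as predictors."""
    targets = {}
    for col in ("bmi", "intensity", "duration", "time_since_cessation"):
        if col in df.columns and df[col].isna().any():
            targets[col] = "linear"
    if not targets:
        return [df]
    ever = df["smoking_status"].isin(["former", "current"])
    sub = pd.DataFrame(
        {
            "age": df["age"].to_numpy(dtype=float),
            "male": (df["sex"] == "male").to_numpy(dtype=float),
            "mets": df["mets"].to_numpy(dtype=float),
            "ever": ever.to_numpy(dtype=float),
        },
        index=df.index,
    )
    smoking_dims = {"intensity", "duration", "time_since_cessation"}
    for col in targets:
        vals = df[col].astype(float)
        if col in smoking_dims:
            # only meaningful among ever smokers; never smokers stay 0
            vals = vals.where(ever, 0.0)
        sub[col] = vals
    spec = ImputationSpec(
        m=config.imputation_m,
        n_iterations=config.imputation_iterations,
        variable_models={c: "linear" for c in targets},
        seed=config.seed,
    )
    completed = chained_impute(sub, spec)
    out = []
    former = (df["smoking_status"] == "former").to_numpy()
    current = (df["smoking_status"] == "current").to_numpy()
    for comp in completed:
        d = df.copy()
        for col in targets:
            was_missing = df[col].isna().to_numpy()
            vals = comp[col].to_numpy(dtype=float)
            # repair invariants on the imputed entries only
            if col == "intensity":
                vals = np.where(was_missing, np.clip(np.round(vals), 1, 60), vals)
            elif col == "duration":
                vals = np.where(was_missing, np.maximum(vals, 1.5), vals)
            elif col == "time_since_cessation":
                vals = np.where(was_missing & former, np.maximum(vals, 1.0), vals)
                vals = np.where(was_missing & current, 0.0, vals)
            if col in smoking_dims:
                vals = np.where(ever.to_numpy(), vals, 0.0)
            d[col] = vals
        out.append(d)
    return out


def _analysis_tables(df: pd.DataFrame, config: StudyConfig, covariates: Sequence[str]):
    codings, table2 = {}, {}
    ever = df["ever_smoker"].to_numpy(dtype=bool)
    for scheme in config.schemes:
        vcol = SCHEME_VALUE_COLUMNS[scheme]
        coding = make_coding(df[vcol].to_numpy(), ever, scheme)
        codings[scheme] = coding
        table2[scheme] = category_association(
            df, coding, vcol, "ever_smoker", "mets", covariates
        )
    table3 = {}
    csi_coding = codings.get("csi_tertiles")
    if csi_coding is not None:
        for comp in ("obesity", "glucose", "blood_pressure", "triglycerides", "hdl"):
            col = f"flag_{comp}"
            sub = df[df[col].notna()].copy()
            sub[col] = sub[col].astype(int)
            table3[comp] = category_association(
                sub, csi_coding, "csi", "ever_smoker", col, covariates
            )
    table4 = {}
    if csi_coding is not None:
        for mod in config.modifiers:
            if mod not in df.columns or df[mod].nunique() < 2:
                continue
            # the categorical a modifier dichotomises is collinear with it
            cov = tuple(c for c in covariates if c not in MODIFIER_SOURCE.get(mod, ()))
            table4[mod] = interaction_analysis(
                df, csi_coding, "csi", "ever_smoker", mod, "mets", cov
            )
    return codings, table2, table3, table4


def _select_covariates(df: pd.DataFrame, config: StudyConfig) -> tuple:
    if config.covariate_policy == "common":
        return tuple(c for c in COMMON_COVARIATES if c in df.columns and df[c].nunique() > 1)
    preset = config.covariates or PROFILE_COVARIATES.get(config.profile, COMMON_COVARIATES)
    preset = tuple(c for c in preset if c in df.columns and df[c].nunique() > 1)
    if config.covariate_policy == "fixed":
        return preset
    if config.covariate_policy == "stepwise":
        candidates = config.stepwise_candidates or preset
        candidates = tuple(c for c in candidates if c in df.columns and df[c].nunique() > 1)
        return tuple(stepwise_select(df, "mets", list(candidates)))
    raise ValueError(f"unknown covariate_policy {config.covariate_policy!r}")


def load_participants(path: str) -> pd.DataFrame:
    """Read a headered delimited participant table (tab or comma)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the configured study end to end (see module docstring)."""
    criteria = _criteria(config.criteria)
    if config.input_path:
        df = load_participants(config.input_path)
    else:
        spec = CohortSpec.from_profile(config.profile, n=config.n, seed=config.seed)
        df, _ = generate_cohort(spec)

    df = add_phenotype(df, criteria)
    df, tally = filter_eligible(df, config.profile, criteria)

    if config.impute == "mice":
        datasets = _mice_datasets(df, config)
    else:
        datasets = [df]

    params = CsiParameters(sensitivity_lag=config.lag_years)
    datasets = [
        add_modifiers(
            add_exposure(d, params, intensity_median_replace=(config.impute != "none")),
            config.profile,
        )
        for d in datasets
    ]
    primary = datasets[0]
    analysis_ok = ~primary[["csi", "pack_years"]].isna().any(axis=1)
    datasets = [d.loc[np.asarray(analysis_ok)].reset_index(drop=True) for d in datasets]
    primary = datasets[0]
    tally["dropped_incomplete_exposure"] = int((~analysis_ok).sum())

    covariates = _select_covariates(primary, config)

    per_dataset = [_analysis_tables(d, config, covariates) for d in datasets]
    codings, table2, table3, table4 = per_dataset[0]
    if len(per_dataset) > 1:
        table2 = {
            scheme: _pool_tables([res[1][scheme] for res in per_dataset])
            for scheme in table2
        }
        table3 = {
            comp: _pool_tables([res[2][comp] for res in per_dataset])
            for comp in table3
        }

    if config.bonferroni and len(table2) > 1:
        # family = the smoking variables tested against MetS
        k = len(table2)
        table2 = {
            scheme: dataclasses.replace(
                at,
                trend_p=at.trend_p if np.isnan(at.trend_p) else float(min(1.0, at.trend_p * k)),
            )
            for scheme, at in table2.items()
        }

    cat_vars = [
        c for c in ("sex", "alcohol", "exercise", "diet", "province", "region", "sports_like")
        if c in primary.columns
    ]
    table1 = descriptive_table(
        primary, "mets_status", continuous=("age", "bmi"), categorical=cat_vars
    )

    result = StudyResult(
        config=config,
        exclusions=tally,
        covariates_used=covariates,
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        codings=codings,
        n_analysis=len(primary),
    )

    if config.sensitivity_lag3 and config.lag_years == 0:
        lagged = [
            add_modifiers(add_exposure(d, CsiParameters(sensitivity_lag=3.0)), config.profile)
            for d in datasets
        ]
        _, t2_lag, _, _ = _analysis_tables(lagged[0], config, covariates)
        result.sensitivity["lag3"] = t2_lag
    if config.sensitivity_common_covariates and config.covariate_policy != "common":
        common = tuple(
            c for c in COMMON_COVARIATES if c in primary.columns and primary[c].nunique() > 1
        )
        _, t2_common, _, _ = _analysis_tables(primary, config, common)
        result.sensitivity["common_covariates"] = t2_common

    if config.out_dir:
        write_report_bundle(result, Path(config.out_dir))
    return result


def write_report_bundle(result: StudyResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table1.to_csv(out_dir / "table1_descriptives.tsv", sep="\t", index=False)
    _association_frame(result.table2).to_csv(
        out_dir / "table2_smoking_mets.tsv", sep="\t", index=False
    )
    if result.table3:
        _association_frame(result.table3).to_csv(
            out_dir / "table3_components.tsv", sep="\t", index=False
        )
    rows = []
    for mod, ir in result.table4.items():
        for stratum, at in ir.strata.items():
            t = at.table.copy()
            t.insert(0, "stratum", stratum)
            t.insert(0, "modifier", mod)
            t["trend_p"] = at.trend_p
            t["p_interaction"] = ir.wald_interaction_p
            t["reri"] = ir.reri.reri
            t["reri_ci_low"] = ir.reri.ci_low
            t["reri_ci_high"] = ir.reri.ci_high
            rows.append(t)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out_dir / "table4_interactions.tsv", sep="\t", index=False
        )
    for name, tables in result.sensitivity.items():
        _association_frame(tables).to_csv(
            out_dir / f"sensitivity_{name}.tsv", sep="\t", index=False
        )
    codings = {
        scheme: dict(cutpoints=list(c.cutpoints), labels=list(c.labels),
                     category_medians=c.category_medians)
        for scheme, c in result.codings.items()
    }
    (out_dir / "codings.json").write_text(json.dumps(codings, indent=2))
    cfg = dataclasses.asdict(result.config)
    manifest = dict(
        package_version=__version__,
        config=cfg,
        config_hash=hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        exclusions=result.exclusions,
        covariates_used=list(result.covariates_used),
        n_analysis=result.n_analysis,
        versions={m.__name__: m.__version__ for m in _dep_modules()},
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _dep_modules():
    import numpy, pandas, scipy, statsmodels

    return (numpy, pandas, scipy, statsmodels)
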