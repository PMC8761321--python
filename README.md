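# smokemets

Tools for studying the association between **life-course cigarette
smoking** and the **metabolic syndrome (MetS)** in cross-sectional survey
data, built around a discovery–replication workflow: an exposure model is
fitted in one cohort (urban adults aged ≥ 60) and re-tested with the same
protocol in an independent adult sample.

Because the underlying participant-level survey records (TNCHS; CHNS) are
restricted, the package ships a fully parameterised **synthetic cohort
generator** with known ground truth, so that every stage of the analysis
— exposure scoring, phenotype classification, adjusted models,
interaction and missing-data handling — is testable end to end.

## The model

Lifetime smoking is summarised by the **comprehensive smoking index
(CSI)**, which combines intensity *int* (cigarettes/day), duration *dur*
(years) and time since cessation *tsc* (years) with an exposure half-life
τ and a lag δ excluding the most recent exposure:

```
CSI = (1 − 0.5^(dur*/τ)) · 0.5^(tsc*/τ) · ln(int + 1)
tsc* = max(tsc − δ, 0),   dur* = max(dur + tsc − δ, 0) − tsc*
```

with τ = 25 y and δ = 0.5 y fixed a priori. Pack-years
(`int · dur / 20`) and fixed intensity bins are provided alongside.
Ever smokers are split at the data-dependent CSI tertiles, never smokers
are the reference, and a multivariable logistic model yields adjusted
odds ratios OR = exp(β) with Wald 95% CIs; linear trend is tested by
entering each category's median as a single continuous term.

MetS is classified by the Chinese Diabetes Society 2013 rule (≥ 3 of:
waist ≥ 90/85 cm (M/F); FPG ≥ 6.1 mmol/L or glucose medication;
BP ≥ 130/85 mmHg or antihypertensive medication; TG ≥ 1.7 mmol/L;
HDL < 1.04 mmol/L), with an explicit **indeterminate** state whenever
missing components leave the diagnosis undecidable under every
completion. Effect modification is assessed multiplicatively (joint Wald
test on category × modifier terms) and additively via
**RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1** with a delta-method CI. Missing
covariates are handled by chained-equation multiple imputation with
Rubin pooling (or the simpler ever-smoker median-replacement rule).

## Worked example

```bash
smokemets analyze --profile discovery_like --seed 5 --out bundle/
smokemets report bundle --table 2
```

prints (synthetic discovery-like cohort, n = 15,222, adjusted for age,
physical activity, BMI and diet; first rows shown):

```
         variable  category  n_cases  n_total  odds_ratio   ci_low  ci_high      trend_p
           status     never     3106    13739    1.000000      NaN      NaN          NaN
           status    former       23       94    1.073990 0.652286 1.768325          NaN
           status   current      449     1389    1.727112 1.524092 1.957175          NaN
   intensity_bins     never     3106    13739    1.000000      NaN      NaN 1.228115e-17
   intensity_bins       1-9       96      354    1.313614 1.024751 1.683904 1.228115e-17
   intensity_bins     10-19      212      651    1.703673 1.427245 2.033641 1.228115e-17
   intensity_bins      >=20      164      478    1.959018 1.599874 2.398784 1.228115e-17
```

Reading: roughly 23% of the cohort is MetS-positive; current smokers
have ~1.7-fold higher adjusted odds of MetS than never smokers, former
smokers show no clear excess, and the odds rise monotonically with daily
intensity — the dose–response pattern the CSI is designed to capture.
The bundle also contains descriptives (table 1), per-component
associations (table 3), stratified/interaction results with RERI
(table 4), codings, sensitivity re-runs (3-year exposure discount,
common covariate set) and a reproducibility manifest; re-running with
the same seed reproduces every file byte for byte.

Library use mirrors the CLI:

```python
from smokemets import CohortSpec, generate_cohort, run_study, StudyConfig

spec = CohortSpec.from_profile("discovery_like", n=15222, seed=5)
frame, truth = generate_cohort(spec)         # truth holds the exact DGP
result = run_study(StudyConfig(profile="discovery_like", seed=5))
print(result.table2["csi_tertiles"].table)
```

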