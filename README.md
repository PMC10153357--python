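# redtia

**Accuracy and uncertainty of reduced-time-point time-integrated-activity
estimation for radiopharmaceutical dosimetry.**

Patient-specific dosimetry after a radiopharmaceutical therapy such as
¹⁷⁷Lu-DOTATATE requires the *time-integrated activity* (TIA) of each organ and
tumor — the integral of its activity over time, later multiplied by S-values
to obtain absorbed dose.  The gold standard fits a time-activity curve (TAC)
through four or more SPECT/CT scans spread over a week, which is burdensome
for patients and clinics.  `redtia` quantifies what is lost when fewer scans
are used: it implements single-, two- and three-time-point TIA estimators,
sweeps every admissible imaging schedule over realistic virtual-patient
cohorts with SPECT measurement noise, and reports the error and variability
of each schedule so that optimal (and acceptably sub-optimal) imaging times
can be identified.

It is aimed at medical physicists and researchers in internal dosimetry who
want to study imaging-schedule trade-offs, and at method developers who need
a tested reference implementation of the standard estimators.

## The model and estimators

Activity follows a monoexponential washout or a biexponential
uptake-and-washout with effective (biological + physical) rates:

```
A(t) = C e^(−λt)                        TIA = C/λ
A(t) = C (e^(−λ₁t) − e^(−λ₂t)),  λ₂>λ₁  TIA = C (1/λ₁ − 1/λ₂)
```

Four-point reference curves choose between the two families by the Akaike
information criterion, `AIC = n ln(RSS/n) + 2k`.  Reduced-time-point
estimators:

* **Hänscheid** (1 scan): `TIA = A(t)·2t/ln 2` — exact at `t = T_eff` and
  `t = 2 T_eff`, at most ≈ +6.15 % high in between on monoexponential
  kinetics;
* **Madsen** (1 scan): `TIA = A(t)·e^(λ_pop t)/λ_pop` with a configured
  population-average effective decay constant — exact when the patient
  matches the population;
* **2TP**: exact monoexponential inversion through two points;
* **3TP**: unweighted least-squares monoexponential fit.

The Monte-Carlo study draws virtual patients from per-structure truncated
lognormal parameter distributions (derived from a real or synthetic cohort's
reference fits, with the mono/bi mix bootstrapped from the observed fit
types), samples each curve on the schedule grids (hourly for single points;
1770 two-point and 3294 clinic-compatible three-point combinations up to
240 h), perturbs each sample with Gaussian noise whose relative standard
deviation follows a power law in effective activity (fit from repeat phantom
imaging), refits, and summarizes RMSE, mean percent error (MPE), its SD and
mean absolute percent error (MAPE) per schedule.

## Worked example

```python
import numpy as np
from redtia import (
    ExponentialModel, TimeActivitySample, hanscheid_tia, madsen_tia,
    PopulationKinetics, run_simulation_study,
    population_kinetics_from_mapping, DEFAULT_NOISE_MODEL,
)
from redtia.synthetic_data import SyntheticCohortConfig, generate_clinical_cohort
from redtia.cohort_simulation import derive_distribution
from redtia.curve_fitting import select_model_aic

# a kidney washing out with a 50 h effective half-life, imaged at 96 h
truth = ExponentialModel("mono", C=90.0, lambda1=np.log(2) / 50)
sample = TimeActivitySample(96.0, truth.activity(96.0))
print(f"true TIA            {truth.tia():8.1f} MBq·h")
print(f"Hänscheid at 96 h   {hanscheid_tia(sample):8.1f} MBq·h")
print(f"Madsen at 96 h      {madsen_tia(sample, PopulationKinetics('kidney', 50.0)):8.1f} MBq·h")

# synthetic cohort -> reference fits -> cohort distribution -> schedule sweep
curves, _ = generate_clinical_cohort(SyntheticCohortConfig(n_patients=28, seed=1))
fits = [select_model_aic(c.samples) for c in curves
        if c.structure in ("left_kidney", "right_kidney")]
dists = {"kidney": derive_distribution(fits, "kidney")}
res = run_simulation_study(
    dists, population_kinetics_from_mapping(), noise=DEFAULT_NOISE_MODEL,
    n_curves=250, seed=1, families=("2tp",),
)
df = res.summaries()
best = df.loc[df.rmse.idxmin()]
print(f"optimal 2TP schedule ({best.t1_h:.0f}, {best.t2_h:.0f}) h: "
      f"MPE {best.mpe:+.1f}%  SD {best.sd:.1f}%  MAPE {best.mape:.1f}%  "
      f"RMSE {best.rmse:.0f} MBq·h")
worst = df[(df.t1_h >= 144) & (df.t2_h - df.t1_h <= 24)]
print(f"late close pairs (both >=144 h, gap <=24 h): median SD {worst.sd.median():.0f}%")
```

prints

```
true TIA              6492.1 MBq·h
Hänscheid at 96 h     6587.8 MBq·h
Madsen at 96 h        6492.1 MBq·h
optimal 2TP schedule (8, 140) h: MPE +0.8%  SD 1.7%  MAPE 1.5%  RMSE 120 MBq·h
late close pairs (both >=144 h, gap <=24 h): median SD 121%
```

The Hänscheid estimate at 96 h (≈ 2 half-lives) is within 1.5 % of truth; the
Madsen estimate is exact because the population half-life equals the
patient's.  The schedule sweep finds that pairing one early with one late
scan keeps the cohort error near zero with small spread, while two late,
close-together scans are catastrophically noisy — the characteristic failure
mode of two-point fitting.

## Command-line interface

The same pipeline is scriptable via the `redtia` command:

```bash
redtia make-cohort --n-patients 28 --seed 1 -o cohort.csv
redtia noise-fit phantom.csv -o noise.json
redtia fit-reference cohort.csv -o fits.json
redtia derive-dist fits.json -o dists.json
redtia simulate dists.json --noise-json noise.json --seed 1 -o summary.csv
redtia evaluate summary.csv -o reports/
redtia check-schedule 24 96 records.csv
```

Every output carries a `.meta.json` sidecar with the seed and a configuration
hash, and identical seed + configuration reproduce outputs byte for byte.

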