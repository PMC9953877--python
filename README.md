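# bcsurv

Body composition, survival statistics, and obesity/lipid-metabolism
metagene clustering for advanced high-grade serous ovarian cancer (HGSOC)
cohorts.

In HGSOC, routinely acquired CT scans carry prognostic information beyond
BMI: visceral adiposity and central sarcopenia, measured on a single slice
at L4–L5, stratify survival, and so does clustering patients on the
expression of obesity/lipid-metabolism genes. `bcsurv` packages that
analysis chain as a tested library plus CLI for biostatisticians and
clinical researchers who want to apply it to their own cohort tables:

* **`clinical_scores`** — body-composition indices and categorical calls:
  VAT/SCAT, VAT/TAT = VAT/(VAT+SCAT), whole-body adipose tissue mass
  (WBAT = 0.0677·AT<sub>L4–L5</sub> + 2.5177 kg), the psoas-to-L4
  vertebral-body index (PLVI), liver−spleen attenuation (CT<sub>L-S</sub>),
  visceral obesity (VAT ≥ 100 cm², VAT/SCAT ≥ 0.4 or VAT/TAT ≥ 0.285),
  central sarcopenia (PLVI < 0.45), steatosis (CT<sub>L-S</sub> < −20 HU),
  the four BC types from crossing the adiposity and muscle flags, NLR,
  the systemic immune-inflammation index (SIII = platelets × ANC/ALC), and
  the 5-item modified frailty index (mFI-5, high risk at ≥ 1).
* **`survival_stats`** — Kaplan–Meier with Greenwood variance, log-rank and
  Gehan–Wilcoxon tests, Cox proportional-hazards regression (Newton–Raphson
  on the partial likelihood, Efron/Breslow ties), univariate screening, and
  forward stepwise selection with p-to-enter 0.2 — implemented from first
  principles and verified against hand-enumerated risk sets and lifelines.
* **`metagene_clustering`** — consensus KL-NMF (Brunet multiplicative
  updates) over seeded restarts, with cophenetic-correlation /
  silhouette-based rank selection and prognosis-based cluster naming
  (worse median OS → `type_I`).
* **`marker_analysis`** — signal-to-noise marker scoring with a
  phenotype-permutation null (exact enumeration at small n), BH FDR,
  weighted-KS enrichment scores, and hypergeometric over-representation.
* **`synthetic_data`** — cohort and expression generators that reproduce the
  study's statistical structure (adiposity marginals, PLVI lower quartile at
  the sarcopenia cut, Weibull survival with BC-type/response/age hazards,
  planted metagene blocks) so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from bcsurv import (SyntheticCohortSpec, generate_cohort, score_cohort,
                    km_median, logrank_test)

spec = SyntheticCohortSpec(n_subjects=400, seed=11)
cohort = generate_cohort(spec)              # baseline/post/month-12 rows
profiles = score_cohort(cohort)             # BC profiles + indices
base = profiles[profiles.timepoint == "baseline"].merge(
    cohort[cohort.timepoint == "baseline"][["subject_id", "time_months",
                                            "event_os"]], on="subject_id")

groups = []
for name, g in base.groupby("bc_type"):
    t, e = g["time_months"].to_numpy(), g["event_os"].to_numpy(bool)
    groups.append((t, e))
    print(f"{name:16s} median OS = {km_median((t, e)):5.1f} months  (n={len(g)})")
res = logrank_test(groups)
print(f"log-rank chi2 = {res.statistic:.2f}, df = {res.df}, p = {res.p_value:.2e}")
```

prints

```
highA_lowM       median OS =  22.4 months  (n=89)
highA_normalM    median OS =  27.8 months  (n=246)
normalA_lowM     median OS =  19.1 months  (n=15)
normalA_normalM  median OS =  27.1 months  (n=50)
log-rank chi2 = 9.89, df = 3, p = 1.96e-02
```

The four body-composition types differ in overall survival (the simulated
hazard penalizes high adiposity and sarcopenia), and the k-sample log-rank
test rejects equality of the four curves at p ≈ 0.02.

The same analysis runs from the shell, one subcommand per stage, each
writing a run manifest (config, input hashes, seeds, timings):

```sh
bcsurv simulate --seed 11 --n-subjects 400 --out-dir run/
bcsurv bodycomp --cohort run/cohort.csv --out-dir run/
bcsurv survival --cohort run/cohort.csv --profiles run/profiles.csv \
                --group-col bc_type --covariates age,ldh --out-dir run/
bcsurv cluster  --expression run/expression.tsv --panel run/gene_panel.txt \
                --seed 11 --out-dir run/
bcsurv report   --run-dir run/
```

See `docs/methods.md` for the model details, defaults, and limitations.

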