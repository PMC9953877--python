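# Methods

`bcsurv` implements a reusable version of an analysis chain linking CT-derived
body composition, clinical inflammation/frailty indices, and obesity /
lipid-metabolism gene-expression clustering to survival outcomes in advanced
high-grade serous ovarian cancer. Because the underlying clinical cohorts are
not redistributable, every estimator is exercised on synthetic cohorts whose
structure is documented below.

## Body-composition and clinical indices

All imaging inputs are already-measured quantities from a single CT slice at
L4–L5: visceral (VAT) and subcutaneous (SCAT) adipose areas, bilateral psoas
areas, the L4 vertebral-body area (all cm²), and mean liver/spleen attenuation
(HU). Derived indices:

| Index | Definition | Default cut | Inclusivity |
|---|---|---|---|
| VAT/SCAT | VAT / SCAT | 0.4 | ≥ (inclusive) |
| VAT/TAT | VAT / (VAT + SCAT) | 0.285 | ≥ |
| VAT area | — | 100 cm² | ≥ |
| WBAT | 0.0677·AT_L4-L5 + 2.5177 kg | cohort median | ≥ |
| PLVI | (psoas L + psoas R) / L4 body area | 0.45 | < (strict) |
| CT_L-S | liver HU − spleen HU | −20 HU | < (strict) |
| BMI | kg/m² | 25 / 30 (WHO) | ≥ |

Visceral obesity is the disjunction of the three adiposity criteria; missing
criteria are skipped and an all-missing record raises rather than defaulting
to "not obese". Central sarcopenia is PLVI below its cut, which was originally
derived as the cohort lower quartile; `derive_quartile_cut` recomputes such a
cut on any sample with the linear-interpolation quantile (the method is
configurable because quantile conventions differ across software). Crossing
high/normal adiposity with present/absent sarcopenia yields the four
body-composition (BC) types; `normalA_normalM` is the reference and
`highA_lowM` (high adiposity plus sarcopenia) the worst-prognosis type.
Trajectories between timepoints are ordered by the number of adverse flags,
so resolving either flag counts as improvement.

Design choices that were genuinely open:

* **PLVI numerator.** The index description refers to the psoas muscles in
  the plural and its published cut (0.45) matches the bilateral sum against
  typical L4 vertebral-body areas (~13 cm² gives psoas totals of ~6 cm²), so
  the bilateral sum is the default; a single-side-mean mode is exposed in
  `ThresholdConfig.plvi_mode`.
* **Inclusivities.** The obesity criteria are stated with ≥ and are inclusive;
  the sarcopenia and steatosis cuts are stated only as "cut-off values" and
  default to strict `<`. All inclusivities are configuration fields.
* **WBAT "high adiposity" threshold.** No absolute WBAT cut is published; the
  default is the baseline cohort median, with a fixed-kg alternative.
* **Units.** Areas are cm², attenuation raw HU; the schema validator checks
  ranges and enumerations but never infers units from column names.

Inflammation and frailty: NLR = ANC/ALC, SIII = platelets × ANC/ALC, and the
five-item modified frailty index mFI-5 counts the comorbidity flags
(hypertension, diabetes, CHF, COPD, non-independent status) with mFI-5 ≥ 1
flagged as higher risk.

## Survival statistics

`survival_stats` implements the estimators directly from the partial
likelihood rather than wrapping a survival library, so that they can be
verified against hand-enumerated risk sets; `lifelines` appears only as an
independent oracle in the test suite.

* **Kaplan–Meier** with Greenwood variance. Censoring tied with an event time
  is handled after the events (the censored subject stays in that risk set).
* **Log-rank and Gehan–Breslow Wilcoxon** as weighted observed-minus-expected
  statistics with hypergeometric variance at each event time; the Wilcoxon
  weight is the total number at risk, which upweights early differences. The
  k-sample statistic uses a (k−1)-dimensional quadratic form.
* **Cox regression** by Newton–Raphson with step-halving, Efron tie
  correction by default (Breslow optional), convergence when the score
  max-norm drops below 1e-9 within 25 iterations, Wald tests and 95% CIs.
  Monotone likelihood (perfect separation) is flagged when a coefficient
  diverges (|β| > 15 on the log-hazard scale, or exploding standard error);
  the model is returned unconverged rather than silently trusted. Covariates
  are mean-centered internally and the linear predictor max-shifted, both of
  which leave the partial likelihood invariant but improve conditioning.
* **Model building**: a univariate screen (one fit per covariate, sorted by
  p, no multiplicity correction — matching common clinical practice) and
  forward stepwise selection with p-to-enter 0.2 plus unconditionally
  forced-in covariates; the full selection trace is returned so any model is
  reproducible. A bidirectional mode re-tests entered covariates after each
  addition.

A subtlety found while testing: duplicating every record leaves the Breslow
estimate exactly unchanged (risk-set ratios are scale-free) but perturbs the
Efron estimate slightly, because duplication manufactures ties that Efron's
staggered correction treats differently. The test suite asserts the exact
invariance under Breslow and closeness under Efron.

## Consensus NMF metagene clustering

Expression input is log2(x+1)-transformed, upper-quartile-normalized
FPKM-like data restricted to a curated obesity/lipid-metabolism gene panel
(the synthetic default panel has 425 genes). Factorization minimizes the
generalized Kullback–Leibler divergence with Brunet-style multiplicative
updates (uniform random initialization, epsilon floor 1e-12, divergence
non-increasing by construction), stopping when the relative divergence change
over 10 iterations falls below 1e-6 or at 2000 iterations.

Samples are assigned to their argmax metagene row of H (patients, not genes,
are being clustered); the consensus matrix is the mean co-assignment over
seeded restarts (default 30). Final labels come from average-linkage
hierarchical clustering of (1 − consensus) cut at the candidate rank. Rank
selection maximizes the cophenetic correlation between the consensus
dissimilarity and the tree's cophenetic distances, breaking ties by average
silhouette width on (1 − consensus), then by the smaller rank. The number of
clusters is therefore always an output; the two-cluster structure of the
original analysis is something the pipeline recovers on data that contain it.
For a two-cluster solution, `label_clusters_by_prognosis` names the cluster
with the lower Kaplan–Meier median overall survival `type_I` (worse) and the
other `type_II`, flagging exact ties.

Known limitation: when a lower rank merges planted blocks in a way that is
globally preferred by the data (e.g., asymmetric block strengths), the merged
solution can be perfectly stable across restarts, and cophenetic-based
selection will favor the lower rank. This is a property of consensus
stability criteria in general, not of this implementation.

## Marker selection and enrichment

Between-class scoring uses the signal-to-noise ratio
(μ₁−μ₂)/(σ₁+σ₂) with each class σ floored at 0.2|μ| (the standard
comparative-marker-selection convention; constant genes otherwise produce
unbounded scores). Significance is by phenotype (label) permutation —
two-sided on |SNR|, Monte-Carlo p = (1 + #{≥ observed})/(n_perm + 1) so p is
never zero — switching automatically to exhaustive enumeration of label
splits when there are at most `n_perm` of them, in which case p-values are
exact fractions. Multiplicity is handled by Benjamini–Hochberg FDR.

Gene-set enrichment uses the weighted Kolmogorov–Smirnov running sum on the
SNR-ranked list (hits weighted by |score|^p, default p = 1, normalized over
in-set genes; misses decremented uniformly); the enrichment score is the
signed extremum of the walk, and at weight 0 it reduces to the classic KS
statistic on the in-set indicator. The permutation p-value is sign-matched:
the observed ES is compared to same-signed permuted ES values. Fixed-set
over-representation uses the upper-tail hypergeometric probability. This is
deliberately not a full GSEA replication: there is no multi-collection
normalized-ES/FWER machinery.

## Synthetic cohorts

`synthetic_data` generates cohorts with the statistical structure the
analysis assumes, so every estimator can be tested without any download:

* **Adiposity**: VAT ~ lognormal moment-matched to mean 118.1, SD 58.9 cm²;
  VAT/SCAT ~ lognormal matched to 0.49 ± 0.22; SCAT derived from the two.
* **Muscle**: PLVI ~ lognormal matched to mean 0.55, SD 0.15, which places
  the lower quartile near 0.45 (the published sarcopenia cut); psoas areas
  are split from PLVI × L4 area. VAT and PLVI latents are coupled through a
  Gaussian copula with ρ = −0.2, reflecting that obesity and sarcopenia
  coexist more often than independence would imply.
* **Steatosis**: a two-component CT_L-S mixture with an 18% steatosis rate.
* **Survival**: Weibull baseline (shape 1.2, scale 60 months — median
  overall survival in the mid-40s, matching an advanced-stage cohort) with
  multiplicative log-HRs for BC type (0 / 0.3 / 0.4 / 0.7 for the reference,
  single-flag, and double-flag types), response (0 / 0.6 / 1.2), age (+0.2
  per decade over 59), and optionally an expression-cluster effect (0.5 for
  type_I). Censoring is an independent uniform administrative window over
  6–120 months. The exponential special case (shape 1) is available for
  analytic checks.
* **Timepoints**: baseline, post-treatment, and month-12 rows per subject,
  with multiplicative lognormal body-composition drifts.
* **Expression**: V = W·H + Gaussian noise clipped at zero, with genes in
  metagene blocks loading `baseline + separation` (defaults 1 + 4) on their
  own metagene and samples expressing their cluster's metagene; ground-truth
  labels are returned. Default size 425 genes; noise SD 0.5.

Ground-truth columns (`true_bc_type`, `true_log_hr`) ride along so recovery
tests close the loop: a cohort generated with log-HR 0.7 for the worst BC
type is recovered by `cox_fit` within 3 SE at n = 1000.

What the generator does *not* emulate: real RNA-seq marginals (library-size
and gene-length effects, overdispersion), correlated gene modules beyond the
planted blocks, informative censoring, measurement error in CT areas, or
non-proportional hazards. Passing tests therefore demonstrate that the
estimators are correct and that the pipeline recovers planted structure —
not that the original cohort-level effect sizes generalize.

## Problem sizes and numerical choices

The test suite uses deliberately compact problem sizes chosen to make the
Monte-Carlo bands tight enough to be meaningful: consensus-NMF recovery at
425 genes × 200 samples with 20 restarts over ranks 2–5; Cox CI coverage
over 500 replicates at n = 500; the permutation null on 2000 genes with 400
permutations. Quantile method, NMF tolerance/iteration caps, pseudocount,
tie-break rules, and all threshold inclusivities are configuration fields
with the defaults stated above, and every CLI stage logs its effective
configuration and writes a manifest (config snapshot, input hashes, seeds,
software version, timings) on success and failure alike.
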