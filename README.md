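# sirisurv

Prognostic survival modeling for head-and-neck cancer cohorts built around
the **systemic inflammatory response index**,

> SIRI = (absolute neutrophils × absolute monocytes) / absolute lymphocytes,

from a pre-treatment complete blood count. The package implements, as a
tested and reusable pipeline, an analysis strategy in which a flexible
ensemble model is *distilled* into a parsimonious, clinic-facing decision
rule:

1. **Random survival forest.** A log-rank-splitting ensemble (default 1000
   trees, bootstrap resampling, Nelson–Aalen leaf estimates) is fit on
   SIRI, Karnofsky performance status (KPS), body-mass index (BMI) and
   smoking history. Mortality risk scores, out-of-bag C-index,
   time-dependent AUC (IPCW, cumulative/dynamic) and permutation variable
   importance come with it.
2. **Cutoff distillation.** Every split threshold the forest used for a
   continuous variable is extracted; the kernel density of those
   thresholds is compared with the kernel density of the variable's
   training values on a shared grid, and local maxima of the difference
   become candidate cutoffs. Candidates creating groups below 10% of the
   cohort are excluded. This turns the forest's implicit, conditional
   split structure into a handful of explicit thresholds (e.g. SIRI ≈ 3.5,
   BMI ≈ 25 and 30).
3. **Risk tree.** A shallow decision tree (depth ≤ 3, node size ≥ 40) is
   grown on the discretized variables by greedy log-rank splitting over
   category subsets; leaves are ordered by mean forest mortality and
   statistically indistinguishable neighbours are merged into ordered risk
   groups (Group 1 = lowest risk).
4. **Validation statistics.** Kaplan–Meier curves, the k-group log-rank
   test, univariable Cox hazard ratios with Wald CIs (Efron ties), the
   75th-percentile high-risk stratification of forest scores, and
   Holm–Bonferroni control over pairwise group comparisons — all computed
   on a held-out 30% test set that no fitting stage ever touches.
5. **Financial toxicity.** The ordered association between the EORTC
   financial-difficulty item (0–3) and SIRI is tested with the
   Jonckheere–Terpstra trend test (tie-corrected normal, exact, or
   permutation p-values), and log2(SIRI) is modelled on the dichotomized
   FT group (Low = 0–1, High = 2–3) plus confounders by OLS.

Because patient-level data of this kind are private, the package ships a
first-class synthetic-cohort generator (`sirisurv.synthetic`) that
emulates the relevant marginal structure — log-normal SIRI with median
1.34 and IQR (0.88, 2.19), the reported KPS/smoking frequencies,
proportional-hazards survival with *step* effects at plantable cutoffs,
exponential-plus-administrative censoring, and FT labels with a monotone
location shift on log2(SIRI). Every analysis stage is exercised and
validated against planted ground truth.

## Worked example

```python
import numpy as np
from sirisurv import forest, pipeline, synthetic

config = pipeline.PipelineConfig(
    cohort=synthetic.CohortConfig(n_subjects=600,
                                  siri_log_sd=synthetic.SIRI_LOG_SD_WIDE),
    hazard=synthetic.strong_hazard_spec(),   # plants SIRI>=3.5, KPS<=70, ...
    forest=forest.ForestConfig(n_trees=300),
    master_seed=11,
)
report = pipeline.run_pipeline(config)

print("test C-index:", round(report["forest"]["c_index_test"], 3))
print("SIRI cutoffs:", np.round(report["cutoffs"]["siri"]["cutoffs"], 2))
print("BMI cutoffs: ", np.round(report["cutoffs"]["bmi"]["cutoffs"], 2))
print("risk groups: ", report["risk_tree"]["n_groups"])
print("global log-rank p (test):",
      f'{report["validation"]["global_logrank"]["p_value"]:.2g}')
print("high-risk HR (75th pct):",
      round(report["validation"]["high_risk"]["cox"]["hazard_ratio"], 2))
print("Jonckheere trend p:", f'{report["ft"]["jonckheere"]["p_value"]:.2g}')
print("FT-Low effect on log2(SIRI):",
      round(report["ft"]["ols_ft_low"]["beta"], 2))
```

Output:

```
test C-index: 0.597
SIRI cutoffs: [1.04 4.03]
BMI cutoffs:  [24.72 30.58]
risk groups:  3
global log-rank p (test): 0.0017
high-risk HR (75th pct): 2.5
Jonckheere trend p: 5.2e-05
FT-Low effect on log2(SIRI): -0.42
```

Reading: on a 600-subject synthetic cohort with threshold effects planted
at SIRI = 3.5 and BMI = 25, the distillation step recovers cutoffs near
the planted values (4.03 for SIRI; 24.7 and 30.6 for BMI — the extra
maxima are admissible under the 10% rule and the tree decides whether they
matter), the merged tree yields 3 ordered risk groups that significantly
separate held-out survival (log-rank p ≈ 0.002), subjects above the 75th
percentile of predicted risk have 2.5× the hazard of the rest, and SIRI
rises monotonically with the planted FT trend.

The same pipeline is scriptable from the shell:

```bash
sirisurv simulate --n 600 --seed 7 --out cohort.csv
sirisurv run --n 600 --trees 300 --seed 7 --outdir out/
sirisurv fttest --cohort cohort.csv --out ft.json
```

## Layout

| module | contents |
| --- | --- |
| `sirisurv.synthetic` | cohort generator: covariates, step-effect survival, FT labels |
| `sirisurv.features` | SIRI from CBC counts; BMI strata; FT dichotomization |
| `sirisurv.forest` | survival forest, mortality scores, OOB/VIMP, C-index, time-dependent AUC, split extraction |
| `sirisurv.distill` | KDE-based cutoff distillation with the 10% minor-group rule |
| `sirisurv.risktree` | discretization, shallow log-rank tree, leaf merging, group assignment |
| `sirisurv.stats` | Kaplan–Meier, log-rank, univariable Cox, Holm–Bonferroni |
| `sirisurv.ft` | Jonckheere–Terpstra trend test, log2(SIRI) regression |
| `sirisurv.pipeline` / `sirisurv.cli` | end-to-end orchestration and the `sirisurv` command |

See `docs/methods.md` for the statistical details, default parameters and
known limitations.
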