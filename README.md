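# tmetrial

Spatial tumor-microenvironment (TME) biomarker quantification and exact
phase-2 trial statistics for immunotherapy cohorts in mismatch-repair-
deficient (dMMR) gynecologic cancers.

The package is written for translational analysts who receive, for each
patient of a single-arm trial: segmented multiplexed-immunofluorescence
cell tables (cell coordinates plus binary calls for CD8, PD-1, TOX,
FoxP3, PD-L1 and Pax8), clinical outcomes (best overall response, PFS/OS,
24-week progression-free status), and per-patient genomic summaries
(pathogenic mutation flags, nonsynonymous counts, MSIsensor scores,
mutational-signature exposures). It computes, end to end:

* **Phenotype fractions** — gated populations such as dysfunctional
  (CD8⁺PD-1⁺) and terminally dysfunctional (CD8⁺PD-1⁺TOX⁺) T cells, as
  percentages of total nucleated cells or of the CD8⁺ compartment,
  within the tumor compartment, averaged across a patient's specimens.
* **Spatial interaction metrics** — nearest-neighbor distances and the
  *interaction fraction*: the share of target cells (e.g. PD-L1⁺) lying
  within r = 50 µm of any anchor cell (e.g. CD8⁺PD-1⁺),
  `100 · |{t : min_a d(t, a) ≤ r}| / |targets|`, boundary inclusive,
  no edge correction, self-pairs excluded.
* **Association statistics** — Mann–Whitney U (exact for small untied
  groups), Fisher's exact test (minimum-likelihood two-sided rule),
  Pearson χ² with PPV/NPV diagnostics, bottom-tertile dichotomization,
  pairwise-complete correlation with average-linkage clustering, a
  two-covariate logistic benefit model fit by IRLS (exposed as a
  scikit-learn-compatible estimator), and rank-formulation ROC AUC —
  all two-sided, with no multiple-comparison adjustment.
* **Trial endpoints** — simplified RECIST 1.1 best overall response from
  target-lesion sums; ORR/DCR/PFS24 with exact Clopper–Pearson binomial
  intervals (beta quantiles); Kaplan–Meier summaries with Greenwood /
  log(−log) confidence bands; and *exact* operating characteristics of
  Simon two-stage designs by binomial enumeration:
  `P(promising | p) = Σ_{s₁ > r₁} Bin(s₁; n₁, p) · P(S₂ ≥ r + 1 − s₁; n − n₁, p)`.
* **Genomic group comparisons** — TMB (mutations/Mb), MSI-H calls
  (MSIsensor ≥ 3.5), dominant/secondary signature labels (signatures
  6/15/20 = dMMR), and per-gene benefit-association scans.

Because patient-level trial data are not redistributable, the package
ships a first-class synthetic cohort generator (`tmetrial.synthetic`)
producing two patient archetypes — clinical benefit vs no benefit — with
known ground truth for every downstream stage: Poisson cell placement in
tumor-nest discs, archetype-specific dysfunction probabilities,
distance-decay PD-L1 co-localization, exponential survival, and
archetype-specific mutation rates.

## Worked example

Simulate a 25-patient cohort and run the full analysis:

```bash
tmetrial run --seed 1 --out results/demo
cat results/demo/report.txt
```

```
ORR  40.0%  (97.5% one-sided lower bound 21.1%)
DCR  44.0%  (95% CI 24.4–65.1%)
PFS24 rate  52.0%  (lower bound 31.3%)
median PFS  5.8 mo

Simon ORR design attained alpha 0.0134, beta 0.0480

benefit model (n=25): AUC 0.936

parameter associations (Mann–Whitney, two-sided, unadjusted):
                        n_benefit  n_no_benefit  median_benefit  median_no_benefit    mw_p
pct_CD8_PD1_TOX_of_CD8         13            12         36.6667             5.2914  0.0004
frac_PDL1_within50_of_CD8PD1   13            12         58.3333            29.9914  0.0008
median_nn_CD8PD1_to_PDL1       13            12         13.6830            28.5933  0.0004
...
```

Reading the output: 13 of the 25 simulated patients carry the benefit
archetype. The terminally dysfunctional share of CD8⁺ T cells (36.7% vs
5.3% medians) and the fraction of PD-L1⁺ cells within 50 µm of
dysfunctional T cells (58.3% vs 30.0%) separate the groups strongly
(Mann–Whitney p < 0.001); dichotomized at their bottom-tertile cutoffs
and combined in the logistic model they discriminate benefit with
AUC 0.936. The Simon line gives the exact operating characteristics of
the trial's ORR decision rule (stage 1: 23 patients, continue iff ≥ 2
responses; promising iff ≥ 6 of 40; 5% vs 25%): attained type I error
0.0134 and type II error 0.0480.

Individual stages are also available as subcommands (`simulate`,
`phenotype`, `spatial --radius 50`, `biomarker`, `trial`, `design`,
`genomics`); run `tmetrial --help`. Thresholds (interaction radius, MSI
cutoff, dichotomization rule, 2×2 test) live in a single YAML config.

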