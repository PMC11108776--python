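# Methods

This note documents the models, conventions and numerical choices behind
`tmetrial`, and what the synthetic cohort does and does not emulate.

## Cell tables and phenotype gating

A specimen is a table of segmented nucleated cells: 2-D coordinates in
µm (origin arbitrary per slide; geometry is never compared across
slides), a tumor/stroma compartment label, and six binary marker calls
(CD8, PD-1, TOX, FoxP3, PD-L1, Pax8). Intensity thresholding is assumed
to have happened upstream in the image-analysis platform; the package
consumes calls, not intensities.

Phenotypes are conjunctions of required-positive and required-negative
markers, so membership is naturally nested: CD8⁺PD-1⁺TOX⁺ ⊆ CD8⁺PD-1⁺ ⊆
CD8⁺, and fraction estimates inherit that monotonicity. Population
fractions are percentages of total nucleated cells unless a narrower
denominator (e.g. CD8⁺) is requested. The default analysis compartment
is tumor; restricting to it is identical to deleting stroma rows, which
is a tested invariant. When a patient contributed several specimens the
per-patient value is the unweighted mean of per-specimen values
(specimens are not pooled cell-wise, so a large slide does not dominate).
Empty denominators yield missing values with a logged warning, never
exceptions; missing values propagate and are dropped pairwise in group
statistics, with counts logged.

## Spatial metrics

Nearest-neighbor distances are Euclidean within a slide. The interaction
fraction at radius r is the share of target-phenotype cells with at
least one anchor-phenotype cell within r, boundary inclusive. Design
choices, all deliberate:

* **r = 50 µm by default** (configurable). This is a neighborhood of
  2–3 cell diameters and brackets the reported range of T-cell-derived
  IFN-γ action (~30–40 µm), which is the biological rationale for using
  PD-L1 upregulation near dysfunctional T cells as an activation
  surrogate.
* **No edge correction.** The estimator is a plain fraction over the
  analyzed slide area; border effects are left in on purpose, so values
  are comparable to the published analysis convention.
* **Self-pairs excluded.** When target and anchor classes overlap, a
  cell is never its own neighbor, but a coincident *other* cell at
  distance 0 counts. Coordinate duplicates from segmentation are kept.
* **Exactness.** The k-d-tree implementation is required by tests to be
  bit-identical to a brute-force O(n²) scan — not approximately equal —
  on random fixtures.

## Association statistics

All group tests are two-sided and unadjusted for multiplicity, matching
the analysis convention of the trial this pipeline serves. Implemented
in-package (with scipy/statsmodels/scikit-learn used only as independent
cross-checks in the test-suite):

* **Mann–Whitney U**: exact p by enumerating the U null distribution
  (Gaussian-binomial q-Pascal recurrence) when the smaller group has ≤ 8
  observations and there are no ties; otherwise the normal approximation
  with tie-corrected variance and a 0.5 continuity correction.
* **Fisher's exact test**: hypergeometric enumeration with the
  minimum-likelihood two-sided rule (sum of all tables with point
  probability ≤ observed, relative tolerance 1e-7). This rule reproduces
  p = 0.027 for a 6/19-vs-0/14 mutation split, the convention anchor.
* **Pearson χ²** on 2×2 tables, df = 1 upper tail via `erfc`; Yates
  correction optional, off by default. Margin-degenerate tables return
  statistic 0, p 1 with a warning.
* **Dichotomization**: biomarkers are split at the bottom-tertile
  cutoff — the 33⅓rd percentile by linear interpolation of order
  statistics — with "high" meaning strictly above the cutoff. The
  cutoff *rule* is the contract; cutoff values are data-dependent.
* **Correlation/clustering**: pairwise-complete Pearson r (≥ 3 complete
  pairs required), agglomerative average-linkage clustering on 1 − r.
  Columns with undefined correlations are dropped greedily (most
  undefined pairs first) and appended after the clustered leaf order.
* **Logistic model**: maximum likelihood by IRLS; convergence when the
  largest coefficient change < 1e-8, cap 100 iterations; complete
  separation is detected as a coefficient-norm excursion beyond 30 on
  the logit scale and flagged rather than silently returned. The
  two-covariate benefit model (terminal-dysfunction share of CD8⁺ and
  the PD-L1 interaction fraction) is exposed as a scikit-learn-style
  estimator so it composes with sklearn tooling.
* **ROC/AUC**: the rank (Mann–Whitney) formulation with ties counted ½;
  the returned curve steps once per tied-score group so trapezoidal
  integration reproduces the rank AUC exactly. The AUC's p-value is not
  computed.

## Trial endpoints and design

* **Best overall response** uses simplified RECIST 1.1 target-lesion
  rules only: CR at sum 0, PR at ≥ 30% decrease from baseline, PD at
  ≥ 20% increase over the nadir that is also ≥ 5 mm. Assessment stops at
  the first qualifying progression; CR/PR achieved before progression
  take precedence, SD requires no progression ever, and no post-baseline
  assessment is NE. Nodal short-axis rules, non-target/new-lesion logic
  and response confirmation are out of scope.
* **ORR/DCR** exclude NE patients from the denominator. Exact binomial
  intervals are Clopper–Pearson beta quantiles; the one-sided 97.5%
  lower bound equals the two-sided 95% lower bound, and the co-primary
  endpoints are reported with one-sided bounds.
* **PFS24**: benefit iff progression-free and alive at 24 weeks, where
  24 weeks = 24·7/30.4375 = 5.52 months, defined once. Patients lost to
  follow-up or dying before the landmark count as events — including
  response-NE patients, who are excluded from ORR but not from PFS24.
* **Kaplan–Meier** summaries are backed by lifelines (product-limit
  estimate, Greenwood variance, log(−log) confidence bands); the median
  is the first time the estimate reaches 0.5, reported as "not reached"
  (NaN) otherwise. A hand-computed product-limit table is the test
  oracle.
* **Simon two-stage operating characteristics** are exact: stage-1
  binomial outcomes are enumerated and combined with stage-2 binomial
  tail probabilities; no normal approximation at any point. The trial's
  ORR rule (n₁=23, continue iff ≥ 2; n=40, promising iff ≥ 6; 5% vs
  25%) attains α = 0.0134 and β = 0.0480, within its stated 0.025/0.05
  error rates. The PFS24 rule is modeled with the stage-1 denominator of
  17 evaluable patients (continue iff ≥ 5; promising iff ≥ 16 of 40;
  25% vs 50%), following the trial's own wording.

## Genomics layer

The module starts where the upstream pipelines end: mutation pathogenic
flags, nonsynonymous counts and capture size (TMB = count/Mb), MSIsensor
scores (MSI-H iff ≥ 3.5, boundary inclusive), and signature exposure
vectors. Dominant/secondary signatures are the two largest exposures,
ties broken toward the smaller signature id and flagged. The
signature-class map is configurable; the default assigns 6/15/20 → dMMR,
10 → POLE, and takes {1, 5} as the aging-related set — the dMMR set is
the published one, the aging set is this package's assumption since no
enumeration is published.

## Synthetic cohort: what it emulates, and what it does not

Each slide is a 1×1 mm region with five non-clipped circular tumor
nests (radius 150 µm) defining the tumor compartment. Each lineage is a
homogeneous Poisson process (defaults per mm²: 1500 tumor, 150 CD8, 80
Treg, 600 other); tumor (Pax8⁺) cells exist only inside nests, mobile
cells everywhere, with the compartment label set by location. Marker
logic is enforced by construction (PD-1 only on CD8⁺, TOX only on
CD8⁺PD-1⁺, CD8/FoxP3 exclusive, Pax8 never in stroma).

The two archetypes differ in:

* dysfunction: P(PD-1|CD8) = 0.65 vs 0.30, P(TOX|PD-1) = 0.60 vs 0.25 —
  chosen to make a large share of the benefit-arm CD8 compartment
  dysfunctional, preserving the direction and rough magnitude of the
  published contrast;
* PD-L1 spatial coupling: under benefit, P(PD-L1) for tumor/other cells
  is `0.15 + 0.65·exp(−d/40 µm)` with d the distance to the nearest
  dysfunctional T cell; under no benefit it is the constant 0.15. The
  published marginal PD-L1 rates per arm are unknown, so these values
  are calibrated only to preserve the *sign* of the interaction
  contrast, not its printed magnitudes;
* outcomes: exponential PFS with hazard 0.02 vs 0.25 per month
  (medians 34.7 vs 2.8 months), OS = PFS + an independent exponential
  residual (so OS ≥ PFS always), administrative censoring at 42.1
  months, best-response mixes favoring CR/PR under benefit;
* genomics: per-gene Bernoulli rates (MEGF8 0.32 vs 0, SETD1B 0.58 vs
  0.14, shared rates for PTEN/ARID1A/PIK3CA/JAK1/CTNNB1/PTCH1),
  lognormal TMB with log-medians 18.1 vs 14.4 mut/Mb (σ = 0.5), MSI-H
  probability 0.79 in both arms, and Dirichlet exposures dominated by
  dMMR signatures for MSI-H draws.

The default cohort is 25 patients with benefit probability 0.52,
matching the imaging-cohort composition the biomarker analyses assume.
A Poisson-plus-decay-labeling model deliberately avoids a full
attraction/Gibbs point process: it creates exactly the co-localization
signal the estimators must detect, with tractable ground truth. What it
does **not** emulate: cell-intensity distributions, segmentation errors,
holes/necrosis and tissue-boundary geometry, inter-slide staining batch
effects, correlated mutation co-occurrence, and copy-number/indel-level
genomics. Passing tests therefore demonstrate correctness of the
estimators and statistics under a clean generative model, not robustness
to those real-data artifacts.

Reproducibility: one master seed; per-patient child generators derive
from `SeedSequence(master, spawn_key=(patient_index, stream))` with
fixed stream ids for TME, outcomes and mutations, so cohorts are
reproducible under subsetting and every CLI run with the same seed is
byte-identical.

## Problem sizes used in the tests

Acceptance-style checks run at the study's own scale: 20 simulated
cohorts of n=25 for archetype separability (mean AUC > 0.8), 10,000
binomial replicates for Clopper–Pearson coverage at (n=34, p=0.6),
n=2000 for logistic parameter recovery (estimates averaged over five
replicates to damp single-draw noise), 300 seeds for the Fisher
mean-p enumeration check, and 600 simulated trials for the Monte-Carlo
check of the two-stage decision rule against its exact enumeration.

## Known limitations

* RECIST is target-lesion-only; real BOR requires non-target and new
  lesion assessment and confirmation.
* The published tertile cutoffs (41% and 25.6%) and cohort-dependent
  quantities (median NN distances 52 vs 212 µm, AUC 0.897) are functions
  of the study data and are not reproduction targets; the rules that
  produce them are.
* The Mann–Whitney exact path requires an untied sample; heavily tied
  biomarker data always use the corrected normal approximation.
* The landmark confidence method (log(−log)) is a choice; published
  landmark CIs may use other transforms.
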