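# Methods

This note documents the models, defaults and numerical choices behind
`cmcpatterns`, what the synthetic cohorts do and do not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trajectory encoding

A participant's cardiometabolic continuum is represented by the 4-tuple
`(t_HYP, t_DM, t_HD, t_STK)` of onset times expressed as fractions of
that participant's follow-up, with `0 < t_i ≤ 1` and `t_i = 1` for a
disease that never occurred. The encoding keeps absent diseases on the
same bounded scale as late-onset ones, so trajectories with different
disease counts remain directly comparable in one Euclidean space.

Edge conventions:

* **Baseline-prevalent disease** (onset time 0) is rejected, not
  clamped — cohorts of this design exclude such participants, and a
  silent clamp would fabricate an incident case.
* **An event exactly at the end of follow-up** encodes to `t_i = 1` but
  keeps its `occurred` flag, so profiling never conflates it with
  absence. Clustering uses the times only, so such an event is
  indistinguishable from absence *for clustering*, by construction of
  the feature.
* **Ties** (two diseases at the same fractional time) are ordered by the
  canonical disease order HYP < DM < HD < STK and flagged, so reports
  can mark the ordering as ambiguous. This is a package convention;
  visit-based ascertainment can genuinely produce same-day diagnoses and
  no principled ordering exists without finer-grained data.

## Synthetic cohorts

`simulate.stratum_config(dialect, sex)` returns a frozen generative
configuration per stratum (`uk`/`elsa` × `male`/`female`). Reference
anchors: mixing proportions equal the published per-stratum cluster-size
fractions (e.g. Healthy 8490/9242 for UK women, 1981/2870 for Brazilian
men); follow-up is Gaussian (10.9 ± 0.6 y UK, 12.3 ± 0.7 y Brazil);
first-onset windows follow the pattern definitions; Healthy's rare
events are late and isolated, matching the published Healthy-cluster
profiles (ELSA isolated-HYP mean onset ≈ 0.88 of follow-up).

Generation order: covariates → pattern membership → onset times.
Membership is a softmax over per-pattern log-odds: `log(mixing
proportion)` plus centred covariate effects (per SD for continuous
covariates, per level for categorical ones), so with zero effects the
marginal pattern frequencies equal the mixing proportions, and with the
default effects they stay close while membership becomes genuinely
covariate-dependent. Default effect sizes (0.15–0.6 log-odds, 2.5 in
the dedicated strong-driver test scenario) are package conventions with
epidemiologically plausible signs — higher blood pressure toward the
hypertension-first patterns, glucose/HbA1c and family history of
diabetes toward FirstDM, smoking toward FirstHD, university education
toward Healthy. Covariate means/SDs and level frequencies are likewise
documented conventions, not published values.

Two onset-time choices matter and were made once, deliberately:

* **First-onset windows are interior subsets** of the descriptive
  intervals: EarlyHyp draws from (0.05, 0.38], LateHyp from (0.44,
  0.8]. The descriptive intervals (0, 0.4] and (0.4, 0.8] abut; uniform
  draws over abutting windows produce one continuous density plateau
  with no gap at 0.4, so k-means bisects it at an arbitrary
  variance-minimising point and the planted partition is unrecoverable
  in principle. The interior windows create a real density gap while
  preserving the published mean onsets (~0.22 and ~0.62).
* **Secondary diseases onset late in the residual follow-up**:
  `t = t1 + u·(1 − t1)` with `u ~ U(0.6, 1)`. Drawing secondaries
  uniformly over the whole residual window splits the FirstDM and
  FirstHD patterns into two well-separated sub-blobs (disease alone at
  `t_HYP = 1` versus disease→HYP at `t_HYP ≈ 0.4`), and the mean
  silhouette then keeps improving past k = 5 by splitting them. The
  late-delay rule keeps each pattern unimodal. Real cohorts show short
  DM→HYP and HD→HYP gaps in these clusters; emulating that level of
  detail is incompatible with a k-means-recoverable five-pattern
  structure and is a stated limitation (below).

Missingness is MCAR, applied cell-wise to covariates only (never to
outcomes or identifiers), default rate 3%. All randomness flows from one
config seed through named `SeedSequence` substreams (covariates,
membership, times, follow-up, missingness), so stages are independently
reproducible and same-seed runs are byte-identical.

What the simulator does **not** emulate: informative censoring,
competing-risk death, visit-schedule discretisation of onset times,
correlated covariates (each is drawn independently given the pattern
structure), non-MCAR missingness, and within-pattern heterogeneity
beyond the uniform windows. Passing tests therefore show that the
pipeline recovers structure *of this planted kind*; they do not certify
behaviour under real-data pathologies such as informative dropout or
measurement error.

## Pattern discovery

k-means (Lloyd) runs on the raw 4-tuples — no scaling, since all four
coordinates already share the (0, 1] scale — with `n_init = 10` seeded
restarts, keeping the lowest-inertia solution. k is selected by the
average silhouette (Euclidean) over k = 2..8; the full per-k score
table is returned for diagnostics, and a best score below 0.25 triggers
a low-separation warning. Above n = 20,000 the silhouette is computed
on a seeded uniform subsample of that size — a performance convention;
the statistic is a mean, so a 20,000-point estimate of it is tight.

Labeling rules are evaluated in precedence order Healthy → FirstHD →
FirstDM → EarlyHyp → LateHyp with configurable thresholds
(`LabelRuleConfig`). Defaults take the *weakest* bound published across
the four strata, so every reference scenario satisfies its rule:
disease-free fraction ≥ 88% (Healthy); 100% incidence of the defining
disease with first-disease shares ≥ 75% (FirstHD), ≥ 78% (FirstDM),
≥ 92% (Early/LateHyp); and ≥ 95% of hypertension onsets inside the
early (≤ 0.4) or late (0.4–0.8] window. An unmatched cluster is
`Unlabeled`; duplicate labels are kept with `#2`-style suffixes plus a
warning rather than silently dropped.

On emulated strata with the default generator, the Brazilian strata
select k = 5 robustly; the UK strata sit on a knife edge (silhouette
differences < 0.005 between k = 5 and k = 6) because their non-Healthy
clusters are each under ~5% of the stratum, and an occasional k = 6
solution surfaces as a manifest warning instead of being forced to 5.

## Statistics

Pearson chi-square is uncorrected (no Yates continuity correction);
ANOVA is one-way; Kruskal–Wallis applies the tie correction.
Significance is judged at p < .05 with no multiple-testing adjustment —
reports carry raw p-values. Expected chi-square cells below 1 warn
rather than abort. Display percentages round half away from zero at the
printed precision; machine outputs keep full precision. Degenerate
inputs (all values identical, a single observed category) return a null
statistic of 0 with p = 1 rather than NaN.

## Classification

Multiclass random forest under stratified outer CV (default 10 folds ×
5 repeats; quick profile 5 × 2) with inner grid search (default 5-fold;
quick 3-fold) selected by weighted F1. The default grid — trees ∈
{200, 500}, depth ∈ {∞, 10}, min leaf ∈ {1, 5} — is a convention; the
methodology prescribes nested tuning, not a grid.

Leakage control is structural: imputation (median/mode), centring and
scaling, one-hot encoding and SMOTE are all fitted inside whichever
training partition is current — outer-train for the outer loop, each
inner-train for tuning — and test partitions are only ever transformed.
SMOTE upsamples every minority class to the majority count by convex
combinations of a class member and one of its `min(k, class size − 1)`
nearest same-class neighbours (k = 5); singleton classes are skipped
with a warning. Classes rarer than the outer fold count are merged into
one stratum *for splitting only*, keeping true labels for scoring.
Weighted recall equals plain accuracy by construction; both are
reported. Seeds derive from the config seed via
`SeedSequence([seed, repeat, fold])` into inner-split, SMOTE and model
substreams, making the whole procedure reproducible and row-order
invariant.

`leaky_cv_smote_before_split` is a deliberately broken negative control
(oversampling before splitting) retained to demonstrate optimistic bias
on imbalanced data; it must never be used for reporting.

## Explanation

Attributions are exact path-dependent TreeSHAP values (the
polynomial-time recursion over split paths, cover-weighted at
unvisited splits), computed per tree and averaged over the forest in
predicted-probability space, so `base + Σ phi = predict_proba` holds to
float precision for every row and class; tests verify agreement with
brute-force Shapley subset enumeration on small trees. The
path-dependent formulation was chosen over an interventional one
because it is fully deterministic and needs no background-data choice.

Attributions are computed only on each fold's held-out rows and pooled
by simple concatenation, so each participant appears once per repeat;
global importance is the pooled mean absolute attribution per encoded
feature and class (top 10 by default). One-hot levels are reported
individually (`education.university` style); an optional aggregation
sums level attributions back to the parent variable before ranking.
Directionality is summarised by sign concordance: the fraction of rows
where the attribution's sign matches the sign of (value − pooled
median) for continuous features, or the fraction of indicator-1 rows
with positive attribution for one-hot levels; it is NaN for constant
features. Feature columns are aligned on the union over folds (a level
absent from one fold's training data contributes zeros there); fold
models must agree on the class set.

## Pipeline

`run_pipeline` executes simulate → cluster → stats → classify → explain
per configured stratum, writing CSV/JSON analogues of the standard
cohort tables plus a manifest (config hash, seed, stage timings, output
inventory, warnings) that is rewritten atomically and records partial
completion on failure. Outputs are byte-reproducible under a fixed
config and seed; the manifest's wall-clock timings are the one
exception and are excluded from determinism checks. Default problem
sizes in the tests and examples (n = 350–5,000, quick CV profile,
60–100 trees) are the package's chosen demonstration scales; the same
code paths run unchanged at full cohort scale.

## Known limitations

* Secondary-onset timing in the DM-first/HD-first patterns is late by
  design (see above), unlike the short observed DM→HYP gaps; analyses
  of secondary-onset timing on synthetic data inherit this convention.
* The silhouette criterion is scale-dependent at very small minority
  clusters (< ~1.5% of a stratum): sub-percent clusters make k = 5 and
  k = 6 nearly indistinguishable.
* MCAR missingness only; imputation quality under MAR/MNAR is untested.
* Feature importance is conditional on the random forest; other
  classifiers may rank covariates differently, and SHAP directionality
  is descriptive, not causal.
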