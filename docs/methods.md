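# Methods

This note documents the models implemented in `bcsubtype`, the choices made
where the underlying procedures are underdetermined, what the synthetic
data generator does and does not emulate, and the numerical conventions
used throughout.

## Subtype vocabulary

All predictors operate on the four intrinsic subtypes basal, HER2,
luminal A and luminal B, in that fixed canonical order; the order resolves
every tie (nearest-centroid distance ties, exact posterior ties, table
layouts). The normal-like subtype is not part of the vocabulary: a loaded
five-centroid reference model is reduced by dropping any centroid whose
label is outside the four-subtype set. Five-class surrogate taxonomies are
folded into four classes by mapping luminal B/HER2+ to HER2 and luminal
B/HER2− to luminal B, which maximizes agreement with mixture-model
assignments in which HER2 calls are possible for both ER− and ER+ cases.

## Robust percentile scaling

For each dataset and feature separately, the empirical 2.5th and 97.5th
percentiles are mapped to −1 and +1:

    x' = 2 (x − q_low) / (q_high − q_low) − 1.

Percentiles use linear interpolation between the closest order statistics
(numpy's default, the "type 7" convention) — stated explicitly because the
percentile definition is otherwise ambiguous. Values outside the anchors
map outside [−1, +1]; no clipping is applied. Constant features map to 0.
The transform is equivariant under any positive per-feature affine map,
which is exactly why it removes per-gene location/scale batch effects.
Cohorts with a heavily skewed subtype composition should not be scaled in
isolation (their percentiles would be dominated by one subtype);
`pooled_scale` fits the anchors on the column-wise concatenation with a
balanced anchor cohort, applies them to the target only, and discards the
anchor.

## Probeset collapsing

When multiple probesets map to one gene identifier, the probeset with the
largest sample variance (ddof = 1) in the dataset at hand is retained;
exact variance ties break to the lexicographically smaller probeset
identifier so the operation is deterministic. Unmapped probesets are
dropped, and the chosen probeset per gene is recorded as provenance. Gene
identifiers are opaque strings: any mapping table in the documented
tab-delimited format is accepted, and synthetic universes work unchanged.

## Module scores

A module score summarizes a phenotype (ER signalling, HER2 signalling,
proliferation, PGR) as the signed weighted average of unscaled log2
gene-level expression:

    score(s) = Σᵢ wᵢ xᵢₛ / Σᵢ |wᵢ|.

Genes absent from the data are dropped with the denominator renormalized,
provided at least a coverage floor (default 0.5) of the module's genes is
present; below the floor the module is an error, never a silent zero.
Scores are computed on unscaled expression and then robustly scaled per
module column within the dataset — the score columns pass through the same
percentile scaler as a small feature matrix. Module gene lists carry
ER/HER2/PROLIF at minimum; when a list lacks a PGR module, the PGR
phenotype is measured by a fixed single-gene module supplied by the caller.

## SSP — nearest centroid

Centroids are per-gene means of robustly scaled expression over labeled
training samples, restricted to the intrinsic gene list (each subtype needs
at least `min_class_size` = 5 training samples). The default distance is
1 − Spearman correlation, making predictions invariant to any strictly
monotone per-sample transform; Pearson and Euclidean modes are available
(no additional per-sample centering is applied in Pearson mode). Samples
with constant expression across the gene list have undefined correlation
and are treated as maximally distant. Prediction requires all model genes
by default; an explicit intersect mode predicts on the common genes
(minimum 3) and records the reduced count.

## SCM — Gaussian mixture on module scores

A 3-component bivariate Gaussian mixture with full covariances is fitted to
the scaled (ER, HER2) scores by EM (scikit-learn backend; k-means++
initialization, 10 seeded restarts keeping the best log-likelihood,
tolerance 1e−6, covariance regularization 1e−8). Components are labeled by
their means: the component with the largest ER mean is luminal; of the
remaining two, the one with the largest HER2 mean is HER2 and the last is
basal. A fit is rejected as degenerate when any component covariance has
condition number above 1e8, when fewer than 30 samples are supplied, or
when fewer than 10 training samples land in the luminal component.

The luminal A/B split is itself model-based: a univariate 2-component
mixture on the proliferation scores of the luminal training samples, with
the low-mean component meaning luminal A. Prediction takes the maximum
component posterior (exact ties resolve in canonical order) and, for
luminal cases, the posterior under the proliferation split (the exact
equal-posterior point resolves to luminal A). A fixed-threshold split mode
(default cutpoint 0) is provided for users who prefer a deterministic
boundary over a fitted one.

## STG — rule table over marker status

Each of the four markers is dichotomized on the scaled score axis at the
equal-posterior point of a per-marker univariate 2-component Gaussian
mixture — the root of π₁N(x; μ₁, σ₁) = π₂N(x; μ₂, σ₂) between the
component means (found by bisection; with equal variances this reduces to
the closed form midpoint + σ² log(π₁/π₂)/(μ₂ − μ₁)). A score exactly at
the cutpoint counts as underexpressed. Marker mixtures whose means are
closer than a separation floor (0.1), or where one weighted component
density dominates everywhere so no equal-posterior point exists, are
degenerate: the strict mode raises an error advising the threshold
fallback, and an opt-in per-marker fallback (used by the pipeline entry
points) sets that marker's cutpoint to the fixed threshold instead.

The 16-entry rule table is fixed: HER2+ profiles are HER2;
HER2− profiles that are hormone-receptor positive (ER+ and/or PGR+ — the
disjunction treats ER−/PGR+ profiles as luminal-like, the adopted
convention) are luminal A when proliferation is low and luminal B when
high; HER2−/ER−/PGR− profiles are basal. The table is serialized
explicitly in the model JSON so alternative mappings can be loaded; only
totality over the 16 profiles is enforced at load time.

## Consensus sets

Given assignments from a predictor panel over identical samples, the
consensus set retains exactly the samples on which every panel member
agrees, with the agreed label. The default five-member panel is: a
user-supplied reference nearest-centroid model applied to the robustly
scaled cohort; three SCMs fitted unsupervised on the cohort's scaled
module scores (one per module gene list); and one STG fitted on the first
list's scores plus the single-gene PGR module. Consensus construction is
deterministic given the assignments, permutation-invariant in the panel,
and monotone (adding a predictor can only shrink the set).

A consensus set then acts as a supervised training cohort: three SSPs (one
per intrinsic gene list, trained on the consensus labels), three SCMs and
three STGs (fitted on the consensus samples' scores) — nine models, each
tagged with its gene list and source cohort. Expression is scaled, and
scores computed and scaled, within the *full* cohort before restricting to
the consensus samples, mirroring per-dataset preprocessing.

## Concordance

Cohen's κ = (p_o − p_e)/(1 − p_e) from the subtype × subtype contingency
table (canonical label order, zero-padded over the union of observed
labels), with cc = 100 · p_o. Subtype-specific κ binarizes both vectors to
"s vs not-s" first. When p_e = 1 — both raters constant and equal, e.g. a
subtype absent from both binarized vectors — κ is undefined and the result
is returned flagged rather than coerced to 0 or 1; aggregation excludes
flagged results and reports the count. Qualitative bands: κ ≤ 0.2 slight
(including negative values), ≤ 0.4 fair, ≤ 0.6 moderate, ≤ 0.8
substantial, otherwise almost perfect; boundary values fall in the lower
band.

The comparison-partitioning protocol groups predictor pairs into: gene
list differs (same type, same training set), consensus set differs, both
differ, and predictor types differ. Pairs whose validation cohort equals
either model's training cohort are excluded from every aggregate to avoid
an optimistic bias. Group summaries are median / min / max of κ and cc
over the included comparisons — one comparison unit being a (model pair,
validation dataset); even-count medians use the midpoint of the middle
two values.

## Synthetic data generator

The generator emulates the structure the pipeline needs from a real
multi-cohort microarray compendium. For gene g of module m in sample s of
subtype k:

    a_sm = separation · mean[k, m] + η_sm,          η ~ N(0, σ_act²)
    x_gs = scale_dg · (b_g + sign_g · a_sm + λ_g v_sm + ε_gs) + shift_dg

* `mean` encodes the subtype patterns (basal: ER−, HER2−, PROLIF+, PGR−;
  HER2: HER2+; luminal A: ER+, PROLIF−, PGR+; luminal B: ER+, PROLIF+,
  PGR+), scaled by the separation multiplier (default 2, log2 units).
* η is per-sample module-activity jitter (σ_act = 1.0) shared by all genes
  of a module — tumor-to-tumor heterogeneity such as the proliferation
  continuum. It is what keeps module scores imperfectly bimodal: purely
  gene-level noise would average away over a 20-gene module.
* v_sm is a secondary per-module latent factor with per-gene loadings
  λ_g ~ N(0, 1.4²): module genes track their phenotype but also carry
  correlated gene-specific biology, so two gene lists drawn from the same
  module measure the phenotype slightly differently. Without this term,
  predictors built on different gene lists would be artificially
  indistinguishable.
* ε is gene-level noise (Gaussian sd 1.0 by default; a Student-t option
  provides heavier tails), b_g a shared per-gene baseline (N(7.5, 1)).
* Batch effects are a dataset-wide intensity shift plus independent
  per-gene shifts (each N(0, σ_batch), default 0.5) and analogous
  multiplicative scale jitter — affine per gene within a dataset, exactly
  the distortion robust scaling removes.
* A quarter of each module's genes is negatively regulated (sign −1), so
  signed module-score weights are exercised; background genes (120 by
  default) carry no subtype signal.
* Optional replicate pairs are two technical re-measurements (sd 0.3) of
  one underlying sample.
* Default subtype proportions (0.29, 0.10, 0.31, 0.30) reflect the
  composition of typical breast-cancer consensus cohorts; they are
  configurable per dataset.

Synthetic gene lists: per module, each of the three lists keeps a shared
core of the requested overlap fraction (default 0.7) and fills the rest
from disjoint random chunks, so the realized pairwise overlap equals the
requested fraction (at overlap 1 the lists are identical). Intrinsic gene
lists additionally include 20 background genes each — like their real
counterparts they are not pure module-gene lists, which keeps the
nearest-centroid predictors structurally distinct from the score-based
ones.

**What passing tests do and do not show.** The generator is Gaussian with
affine batch effects — the regime in which robust scaling and mixture
fitting are exactly well-specified. Real microarray data add probe-level
effects, intensity-dependent distortions, non-Gaussian tails and
annotation noise that the generator does not emulate (a heavier-tailed
noise option exists but is not the default); results on synthetic data
bound what standardized preprocessing can achieve, not what any particular
public cohort will show.

## The end-to-end concordance experiment

`run_concordance_experiment` simulates 12 cohorts (1 reference + 5
training + 6 validation; 500 samples each, roughly the size of the larger
public breast-cancer cohorts), trains the reference nearest-centroid model
on the held-out cohort with its true labels (standing in for a published
reference predictor), builds one consensus set per training cohort with
the five-predictor panel, trains the nine-model suite on each, applies
every model to every validation cohort, and aggregates all pairwise κ
statistics into the comparison groups. Cohort size matters for the
*relative* cost of design choices: with a few hundred samples per cohort
the sampling noise of the unsupervised consensus-set fits dominates, while
at the default size the gene-list effect emerges as the larger one — the
qualitative pattern the test suite asserts (same gene list ≥ same
consensus set ≥ both differ, with inter-type agreement below all
intra-type medians).

## Numerical conventions and edge cases

* All randomness flows from explicit integer seeds; manifest-driven CLI
  runs refuse stochastic steps without a seed, and identical manifests
  reproduce byte-identical outputs.
* Posteriors sum to 1 within 1e−10; mixture refits with the same seed are
  bit-stable.
* Missing expression values are permitted at probeset level only;
  predictors reject gene-level matrices containing missing values.
* Validation (`validate_matrix`) never raises — it returns a list of
  violation descriptions naming the offending identifiers.

## Known limitations

* The consensus panel's reference model must be supplied (or trained on a
  labeled held-out cohort); no published centroid sets ship with the
  package.
* The STG mixture cutpoint assumes each marker's scaled scores are at
  least weakly bimodal; cohorts with truly unimodal markers require the
  threshold fallback.
* Aggregation units are fixed to (model pair, validation dataset); other
  units of aggregation (e.g. per-pair medians over datasets) must be
  computed from the raw comparison list, which the experiment result
  retains in full.
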