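# Methods

## Problem and model

The package classifies breast-cancer samples into TNBC (ER−, PR−, HER2−;
the positive, minority class, ~16% of patients) versus non-TNBC
(Luminal A: ER+ and/or PR+, HER2−; Luminal B: ER+ and/or PR+, HER2+;
HER2-enriched: ER−, PR−, HER2+), and reports which attributes carry the
separation.

The core learner is the **Set Covering Machine**: a greedy construction
of a conjunction of single-attribute threshold rules ("rays",
`x[a] ≤ t` or `x[a] > t`). With P the positive and N the negative
training examples, each greedy step scores a candidate rule h by

```
U_h = |N_h| − p · |P̄_h|
```

where N_h are the not-yet-covered negatives h classifies correctly (for
a conjunction, negatives on which h is false) and P̄_h the still-active
positives it would misclassify. The argmax rule is appended, covered
negatives and sacrificed positives are removed, and the loop stops when
no negatives remain, when `s` rules have been selected, or when no rule
has U > 0 (a non-contributing rule only costs sparsity). A disjunction
is obtained by fitting a conjunction on complemented labels and
complementing the rules (De Morgan); prediction is AND (conjunction) or
OR (disjunction) over the rules, with the empty conjunction vacuously
positive.

**Candidate rules.** Thresholds are midpoints between consecutive
distinct sorted training values per attribute, both directions;
constant attributes contribute nothing. This data-dependent ray set is
the canonical construction and is exhaustively enumerable, which the
tests exploit: the vectorized greedy step is checked rule-for-rule
against a brute-force argmax on small instances.

**Determinism.** Utility ties break by larger |N_h|, then smaller
attribute index, then smaller threshold, then the "≤" direction. With
this ordering the whole pipeline is a pure function of its seeds.

**Hyperparameters.** p ≥ 0 (sacrifice penalty) and s ≥ 1 (early-stopping
rule cap) are selected by stratified 5-fold cross-validated F1 on the
training split over p ∈ {0.1, 0.316, 1, 3.16, 10} × s ∈ {1,…,5} — a
half-decade-spaced penalty grid around 1 and all useful model sizes.
Because the greedy path for fixed p does not depend on s, each fold is
fitted once per penalty and the s values are scored as prefixes. F1 is
the selection metric throughout: with a 16% positive class, accuracy is
dominated by the majority class.

## Feature-space assembly

* **Methylation fusion.** The two array platforms are merged over the
  union of probe ids; for shared probes the higher-resolution (450K-style)
  platform wins where observed and the other platform fills its gaps
  (configurable precedence). An entry is missing only where both are.
* **Label-conditional imputation.** Each missing entry is filled with
  the mean of the attribute's observed values among samples of the same
  binary label; a class with no observation falls back to the overall
  column mean, an entirely unobserved column to 0 (a total function —
  no silent NaN propagation). The statistics are computed on the full
  cohort *before* splitting, reproducing the modeled preprocessing
  order. This leaks label information into the matrix by construction;
  it is a property of the procedure being modeled and is documented
  rather than corrected. Imputation is idempotent and never alters
  observed values.
* **Concatenation.** Views concatenate in input order with globally
  unique `view::attribute` ids and a registry mapping every column to
  (view, attribute, gene symbol), so learned features can always be
  traced back. Full-scale widths: 73,599 + 1,046 + 23,381 = 98,026.

## Repeated-holdout protocol

Each repeat draws a stratified 80/20 train/test split (per class,
⌊0.8·n_class⌋ to train; leftover slots by largest fractional remainder;
sample assignment by a seeded per-class shuffle). Per repeat the SCM is
tuned and fitted as above; the decision-tree and random-forest baselines
use scikit-learn defaults (forest: 100 trees) with per-repeat random
states — the bespoke science is the SCM, the protocol and the counting,
not a reimplementation of CART. The full design is 100 repeats; the
desk-scale runs in tests and in `scripts/acceptance.py` use 20.

**Ten best models and feature counting.** Per algorithm, the ten models
with the best held-out F1 (ties: held-out accuracy, then lower repeat
index) are retained. Each model contributes each of its distinct
attributes once: the SCM its conjunction's attributes in selection
order; a tree its first three distinct split attributes breadth-first
from the root (root-proximal splits are the most informative under
CART's greedy criterion; depth-first order is available as an option);
a forest the per-tree first-three sets pooled and deduplicated per
model. Attribute counts roll up to genes by the maximum over the gene's
isoform attributes — a gene is as supported as its best isoform — and
each counted attribute receives a direction call by comparing class
means (up_in_tnbc / down_in_tnbc / unchanged on exact equality).
Selection by held-out (not training) F1 is a deliberate choice
consistent with the protocol's train/test design.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not the
biology of any real dataset:

* **Classes.** Subtype counts by largest-remainder rounding of the
  configured fractions (defaults 16/63/16/5%); at n = 877 this yields
  exactly 140 TNBC / 737 non-TNBC. Receptor combinations are drawn
  uniformly among those consistent with each subtype; labels satisfy
  label = 1 ⟺ triple-negative.
* **Values.** Background attributes are i.i.d. Gaussian, mean 0,
  sd = `noise_sd` (default 1), class-independent — a log-like continuous
  scale. Threshold rules are monotone-invariant, so any continuous
  unimodal background exercises the learner equally. Planted attributes
  (defaults: 15 down + 5 up, one isoform per planted gene) receive a
  ±δ·noise_sd mean shift in the TNBC class, δ = 2 by default — a strong
  but overlapping separation (single-attribute Bayes error ≈ 16%).
* **Missingness** is independent Bernoulli at `missing_rate`
  (default 0.1) and confined to the methylation views.
* **Streams.** One master seed spawns a CRC-keyed substream per view,
  so adding or removing a view never perturbs the others; identical
  configs reproduce cohorts bit for bit.
* **Not emulated:** real expression distributions (counts/RSEM and
  their transforms), inter-attribute correlation, batch and platform
  artifacts, isoform-level correlation within a gene, survival times.
  Passing recovery tests therefore demonstrates that the machinery
  finds planted mean-shift signals under class imbalance and
  methylation missingness — not that it would rank real genes
  identically.

**Desk-scale problem sizes.** Recovery runs use 400-sample cohorts with
~2,000 attributes (1,800 isoforms in 600 genes at 3 isoforms/gene, 100
miRNAs, 120 methylation probes fusing to 100), 20 repeats and 5 master
seeds, with the top-20 gene rows scored against the 20 planted genes.
These sizes keep the full protocol in the minutes range while leaving
the planted-to-background ratio (20 in 2,000) sparse enough to be a
real search problem.

## Interactor filtering

SAINT-style tables are parsed with tolerant, case-insensitive column
matching (malformed rows skipped with line numbers; a missing mandatory
column is a named error). Filters: BFDR ≤ 0.01 and contaminant
frequency ≤ 20 of 411 negative controls, both boundaries inclusive;
preys absent from the contaminant profile pass (absence of evidence of
contamination). Counts are distinct prey genes, not rows. The overlap
report partitions AP-MS/BioID gene sets and annotates membership in a
known-interactor list.

Because the original supplementary tables are external downloads, the
package ships a **synthetic replica generator**
(`synthetic_saint_screen`): tables whose per-row values are random but
whose composition (significant genes per assay, contaminated fraction,
known-interactor placement) mirrors two published bait screens (TBC1D9,
MFGE8). Filter outputs on these tables are recomputed, not asserted;
they land on the published counts (68→52 and 77→67; 138→123 and 12→9)
exactly when the chain's boundary conventions are right, which is what
the tests check.

## Numerical and design notes

* Utilities are exact: counts are small integers in float64, so
  tie comparison by equality is safe.
* The greedy scan sorts each column once per fit (reused across CV
  penalties) and scores all thresholds by cumulative sums; columns are
  processed in blocks of 4,096 to bound memory.
* The separable-recovery property (δ = 3 cohorts solved to training
  F1 = 1 with ≤ 2 rules) is tested on small cohorts (60 samples, five
  planted attributes) with a sacrifice-averse penalty p = 5: perfect
  two-rule separation of overlapping Gaussians is only statistically
  guaranteed when the negative class is small relative to the
  per-attribute overlap probability, and a small penalty would trade
  positives away for coverage.
* Model serialization writes a human-readable rule list plus a JSON
  sidecar; round-trips are exact (Python repr floats).
* `split_train_test` errors on classes with fewer than two samples;
  metric edge cases follow the precision/recall/F1 → 0 convention on
  empty denominators.

## Limitations

Real-data mode expects preprocessed delimited matrices; no
normalization, probe annotation or beta/M-value conversion is applied
beyond the imputation described. Survival analyses, external cohort
validation, enrichment analysis and upstream mass-spectrometry scoring
are out of scope; SAINTexpress output is consumed, never recomputed.
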