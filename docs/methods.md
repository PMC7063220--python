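# Methods

## Scope and data model

The package reimplements, as a reusable pipeline, a network-pharmacology
analysis of a 15-herb formula acting on two pathological processes of the
blood-stasis phenotype: hemorheological abnormality and coagulopathy.  Its
inputs are flat tables rather than live database queries: a compound table
(herb attributions plus OB, Caco-2 and DL columns), a compound–target
prediction table with per-source scores, a target→module annotation table,
GMT gene-set collections, and an animals × indices cohort matrix.  The
external QSAR models that produce OB and Caco-2, and the database mining
itself, are out of scope; their outputs are consumed as columns.

## Screening

Drug-likeness is the Tanimoto coefficient
`T(A,B) = A·B / (‖A‖² + ‖B‖² − A·B)` between a compound's descriptor vector
and a reference vector of average drug properties, applied to non-negative
descriptors on a fixed shared schema.  The reference vector is a caller
input: the descriptor set and drug-average vector behind published DL
columns are not public, so per-compound DL values from upstream databases
are not recomputable; the implementation is validated analytically
(identity, symmetry, bounds, hand-evaluated cases) instead.  When a
compound carries both a precomputed `dl` column and a descriptor vector,
the precomputed value wins (matching upstream provenance); a flag forces
recomputation.

The ADMET gate retains a compound iff OB ≥ 30 % and Caco-2 ≥ −0.4 and
DL ≥ 0.18, or it is whitelisted.  The three thresholds are inclusive (the
rule is phrased as "≥" and "less than −0.4 not permeable"), while the
predictor gates (Max TC > 0.57, probability > 0) are strict; both
conventions are configuration, not hard-coded.  Malformed compounds are
collected as per-record errors and skipped — a database extract should not
abort a run.

## Networks

Module networks are undirected, unweighted tripartite graphs; herb–target
and within-layer edges are integrity errors.  Degree is the incident-edge
count within the module network, so a compound's degree includes its herb
attributions; a `target_degree` column exposes the interaction-only
counting, since published top-10 tables are consistent with the former
while the prose counts the latter.  Betweenness uses Brandes' algorithm
(networkx) on the undirected graph, normalized by `(n−1)(n−2)/2` over the
whole network's node count — the convention of common network-visualisation
tools, which keeps values in [0, 1]; raw values are available by flag.  The
implementation is cross-checked in the test suite against an independent
brute-force oracle that enumerates all shortest paths on random ≤ 15-node
graphs.  Ranking ties break by the secondary centrality, then node id, so
top-k tables are deterministic.

Cross-module overlaps are computed either from membership sets or from
printed sizes via inclusion–exclusion (`|A∩B| = |A| + |B| − |A∪B|`), with
inconsistent size triples rejected.

## Enrichment

Over-representation uses the one-sided hypergeometric tail `P(X ≥ k)` with
X ~ Hypergeometric(N, K, n): query size n, category size K, background N,
overlap k.  The upstream analysis delegated this step to the DAVID web
service without printing its statistic; the standard hypergeometric test is
the implemented default, and DAVID's EASE variant (one overlapping gene
discounted, `P(X ≥ k−1)`, with k ≤ 1 ⇒ p = 1) is available as a mode.
Benjamini–Hochberg FDR is applied across the tested (k ≥ 1) categories —
the upstream analysis states no adjustment, so raw p-values are reported
alongside.  The background defaults to the union of annotated genes and is
configurable.  Exact DAVID term lists and counts are database-version
dependent and are not reproduction targets.

## Chemometrics

Preprocessing is unit-variance autoscaling (mean 0, SD 1, ddof = 1), the
default of the reference chemometrics software; the original analysis does
not state its scaling, so it is exposed as configuration.  PCA is computed
by SVD of the centered matrix; its Q² uses venetian-blind row folds with
reconstruction PRESS over projections onto the training loadings.

PLS-DA fits NIPALS PLS2 of the autoscaled X against the column-centered
one-hot class matrix: per component, the weight vector w (unit norm),
scores t = Xw, Y-loadings c, X-loadings p, then deflation of X and Y by
t.  R²X and R²Y are cumulative explained sums of squares; Q² is
cross-validated with venetian-blind folds (default 7), refitting scaling
and model on every training split and accumulating PRESS/TSS on the
held-out rows.  Component extraction stops early if the Y residual is
numerically exhausted.  The in-sample predictions are cross-checked in the
tests against scikit-learn's independent PLS2 implementation.

VIP follows the standard definition
`VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a)` so that Σ VIP² = p;
variables with VIP > 1 contribute more than average to class separation.

Permutation validation refits the model under (default) 200 random label
permutations; the model is valid when every permuted R²Y and Q² falls below
the unpermuted values.  Intercepts are reported from a straight-line fit of
the permuted statistics against the permuted-vs-original label correlation
(the unpermuted model enters at correlation 1).  CV-ANOVA, a proprietary
formulation of the reference software, is deliberately not implemented;
permutation testing covers model validity.

Group effects are ranked by the Euclidean distance of each group's centroid
to the reference (control/normality) centroid in score space.  One-way
ANOVA is reconstructed exactly from group summaries (means, SDs, sizes):
between-group SS from means and sizes, within-group SS from SDs; pairwise
comparisons against the control and the disease-model group use Welch's
t-test from the same summaries (the original post-hoc procedure is
unnamed), flagged at p < 0.05 / p < 0.01.

## Synthetic benchmarks

`generate_cohort` draws each index independently from Normal(mean, SD) per
group.  Only per-group means ± SD are published, so independence across
indices is the default; a user-supplied correlation matrix switches to a
multivariate normal.  `REFERENCE_GROUPS` encodes the published summaries of
all six groups (control, model, three formula doses, positive-control
drug); group size defaults to 8 animals, configurable because the published
tables note n = 6–8 without per-group attrition.  One printed SD ("012")
was read as 0.12.

`generate_universe` emits ADMET values that straddle the gate thresholds
(pass/fail drawn per compound with probability `frac_pass_admet`, each
failing compound failing at least one criterion), a small whitelist among
the failing compounds, heavy-tailed compound→target degrees (truncated
Zipf, background ≈ 2–3) with skewed target popularity, module labels per
target (hemo-only/coag-only/both in proportions mirroring a 51/68/17-of-102
split), and pathway gene sets of 5–30 members.  Planted hub compounds
always pass the gate and receive `hub_target_degree` curated edges, so the
planted degree survives screening and prediction filtering deterministically.
Planted enriched pathways oversample hemorheology-module targets by the
given odds multiplier and are drawn with at least 15 members: a 5-member
category cannot carry a reliably detectable over-representation at moderate
odds, so the benchmark plants its signal where it is identifiable.  The
ground-truth record lists the passing compounds, hubs with post-filter
degrees, module target sets and planted pathways; all generators are pure
functions of their seed.

What the generators do **not** emulate: correlated indices (real blood
viscosity indices are strongly correlated across shear rates), measurement
error structure, compound-level chemistry (descriptors are placeholders),
and the biological coherence of pathway membership.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not recovery guarantees on real cohorts or real
interaction databases.

## Numerical choices

* NIPALS convergence: relative score change ≤ 1e−12, ≤ 1000 iterations
  (two-class problems converge in one step).
* Constant columns are a hard error in autoscaling, named per column.
* Hypergeometric p-values are clamped to (0, 1]; BH preserves input order.
* JSON reports round floats to 9 significant digits and sort keys, making
  repeated runs byte-identical.
* Experiment sizes: replicate-based checks use 100 seeded replicates; the
  VIP experiment uses n = 8 per group to match the published cohort size.

## Known limitations

The published R²/Q²/VIP values and score-plot centers were computed on the
raw animal matrix, which is not deposited; they are reproducible only in
distribution, via cohorts regenerated from the summary statistics.  Under
the independence assumption, the five published VIP-selected indices are
exactly the five with population VIP > 1, but two of them (WBV50, FIB) sit
barely above 1, so at n = 8 an individual replicate will not always select
all five simultaneously.  Enrichment results depend on the annotation
collection supplied; no ontology-graph propagation is performed for GO.
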