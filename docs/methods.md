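# Methods

## Model and assumptions

The method assumes that a perturbed miRNA's footprint in a case/control
transcriptome is a *coherent* sub-signal: a group of co-expressed,
differentially expressed target genes (one transcriptional module),
while the rest of the miRNA's predicted targets behave like background.
Three ingredients make that detectable:

1. a **multi-scale decomposition** of the DE genes into co-expression
   signatures (clusters at every scale of an average-linkage hierarchy),
   so the module is available as a test set at whatever scale it lives;
2. a **weighted overlap statistic** ES_ij that up-weights strong
   predicted targets via rank-discretized context scores; and
3. a **stratified permutation null** that preserves everything about
   the bipartite miRNA–target network except which gene each edge
   touches: per-score-level family degrees and gene degrees are kept
   exactly, so target-set sizes, score composition, and gene popularity
   are all matched in the controls.

The min-p aggregation P_i = min_j p_ij over signatures is deliberately
anticonservative as a raw statistic; its significance is restored by the
nested empirical test (below).  All reported inference is on the
empirical p_i and its BH q-value.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| K, b | 5, 3 | number of score levels and level spacing; levels are 1, 1+b, …, 1+b(K−1) = {1,4,7,10,13} |
| top_n, sample_fraction | 10 000, 0.3 | expression filter: keep genes in the per-sample top `top_n` in ≥ 30% of samples |
| de_alpha | 10⁻⁴ | BH-adjusted p threshold defining the DE set |
| z_cutoff | 0.52 | Fisher z-score of the merge-correlation stopping rule; r\* = tanh(z/√(n−3)); one-sided normal tail ≈ 0.3 |
| min_size, max_size_fraction | 30, 0.8 | signature size bounds (genes; fraction of DE set) |
| dedup_jaccard | 0.9 | signatures with Jaccard ≥ 0.9 to an already-kept one are suppressed |
| R | 10 000 (1 000 for desk-scale runs) | stratified permutation replicates |
| n_swaps_per_edge | 10 | attempted double-edge swaps per edge (rejections count) |
| q_threshold | 0.1 | families reported in the inferred sub-network |

All tunables live in one `RunConfig` object, serialized into every
output directory.

## Numerical conventions

* **Discretization rank.** The score ladder uses 0-based rank,
  s = 1 + b·⌊rK/N⌋, which yields both stated endpoints (1 for the
  weakest 1/K, 1 + b(K−1) for the strongest 1/K).  Ties in context
  score are broken by a stable sort on (gene, family), making the
  assignment deterministic across platforms.
* **Tie handling.** All empirical comparisons use ≥ / ≤ (ties count
  toward significance), the conservative direction.
* **Empirical proportions** are plain #/R, not (#+1)/(R+1).  An
  observed score exceeding every control gives p = 0, written as
  "< 1/R" in output tables.  This choice permits exact-zero q-values
  for decisively enriched families.
* **Nested test economy.** The literal nested procedure would need R²
  permutations.  Instead, each control replicate's per-signature
  p-values are its self-inclusive right-tail ranks within the single
  control ES tensor, p_ij(r) = #{r′ : ES_ij(r′) ≥ ES_ij(r)}/R, and
  P_i(r) = min_j p_ij(r).  Scoring the controls against themselves this
  way gives exactly uniform p-values on {1/R, …, 1} per family (a
  property the test suite checks).  The combination with the #/R
  convention for the observed side leaves one visible artifact at small
  R: an observed set whose ES beats all R controls in *any* signature
  gets p_i = 0 outright, so with J signatures a fraction ≈ J_eff/R of
  null sets lands exactly at zero (≈ 2% at R = 1000 with ~40
  signatures, ≈ 0.2% at the default R = 10 000).  Per-family
  calibration is otherwise exact; see Limitations.
* **Permutation mixing.** The per-level swap budget (⌈10 × level
  edges⌉ attempts) is split into interleaved sweeps across levels,
  because the duplicate-edge check couples the strata: randomizing each
  level to completion in a single pass leaves the joint configuration
  under-mixed.  With interleaving, empirical p-values match exhaustive
  enumeration on small graphs within Monte-Carlo error.
* **Degenerate inputs.** Zero-variance genes get p = 1 in the t-test
  and correlation 0 in the similarity matrix (logged, not fatal);
  levels with fewer than two edges are left untouched by the
  permutation; an empty signature list falls back to the flat DE
  signature (configurable).
* **q-values** are BH step-up.  The original pipeline used fdrtool's
  empirical-null q-values; BH preserves the ranking but absolute values
  can differ, so q's should be compared within a run, not across
  estimators.
* **Signature stability.** Candidate signatures are internal dendrogram
  nodes that persist over a nonzero correlation interval (merge
  correlation differs from the parent's by > 10⁻⁹).  Chains of nodes
  created at one identical correlation are binary-encoding artifacts of
  a flat merge and only their top node is a cluster.
* **Best-signature ties.** When several signatures share the minimal
  p_ij, the smallest one (size-ascending order) is reported.

## Synthetic study conditions

The generator emulates the structure the method assumes, with defaults
chosen once as a realistic desk-scale cancer study:

* 2 000 genes, 30 case + 30 control samples, unit noise;
* 8 disjoint blocks of 60 genes, each a factor-model module
  (x = √ρ·F + √(1−ρ)·ε with ρ = 0.7, expected within-block correlation
  exactly ρ) with a case-group mean shift |δ| = 2 of alternating sign —
  all 480 block genes are DE at the default threshold, background genes
  are i.i.d. noise;
* 100 miRNA families with log-uniform target-set sizes between 20 and
  800 (real miRNA families range from under 50 to over 1 000 targets);
  non-planted families draw targets uniformly over all genes with
  context scores uniform on (−0.6, −0.01);
* one planted family of degree 100: 20 targets inside one block with
  strong scores on (−1.0, −0.8) (top discretization level), the
  remaining 80 drawn from background (non-module, non-DE) genes.

The planted design models a module-specific regulator whose non-module
targets are expressed but unchanged.  Its total DE overlap then matches
the stratified null's expectation, so flat DE-set enrichment (miRDeG)
sees no signal, while the block signature concentrates 20 top-level
targets in 60 genes — the regime in which the hierarchy is the source
of sensitivity.  This is the package's in-silico analog of the method's
central claim, and the recovery tests quantify it (hierarchical q < 0.1
with the flat baseline at q ≥ 0.1, and the reported best signature
overlapping the planted block).

What the generator does **not** emulate: probe/batch effects,
non-Gaussian microarray noise, correlated miRNA families, overlapping
modules, or partial repression (graded rather than shifted targets).
Passing recovery tests therefore demonstrates the statistical machinery
under the stated model, not performance on any particular real dataset.

Validation experiments run at reduced scale to stay desk-sized:
calibration with R = 1 000 and 100 control sets per family (the
uniformity and size-independence checks), sensitivity over 25 seeds at
R = 1 000, and enumeration agreement at R = 10 000 on an 8-edge graph.

## Design choices where the design was open

* **Signature extraction** is only sketched in the original
  description; this package takes all stable internal nodes within size
  bounds with leaf-to-root Jaccard deduplication.  It reproduces the
  expected multi-scale behavior (nested signatures of very different
  sizes coexisting).
* **Linkage similarity** is signed correlation (negatively correlated
  genes never co-cluster); |r| is available via
  `RunConfig(absolute_correlation=True)`.  Pearson is the default,
  Spearman available.
* **t-test flavor** for paired cohorts is ambiguous; the default is
  Welch's two-sample test with `paired=True` switching to the paired
  test.
* **HG-test universe** defaults to the filtered expression gene set.
* **Swap schedule**: only the conserved quantities are prescribed by
  the method; the budget (10 attempted swaps/edge, interleaved sweeps)
  is this package's documented default, validated by the enumeration
  oracle.

## Limitations

* The empirical p floor is 1/R; families beyond it are reported as
  "< 1/R" and tie at q = 0.
* The shared-tensor nested test has the ≈ J_eff/R zero-atom described
  above; at R = 1 000 with many signatures this makes the *pooled*
  distribution of null empirical p-values detectably non-uniform at the
  extreme low end even though each family's distribution passes
  uniformity tests.  Use the default R = 10 000 for final inference.
* BH q-values, not fdrtool local-fdr q-values.
* Expression values are used as provided; normalization and
  probe-to-gene mapping are out of scope.
* Bootstrap stability labels and GO annotation of signatures are not
  implemented.
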