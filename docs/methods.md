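# Methods

## Problem setting and model

The pipeline combines several small treated-vs-control expression
studies of one tissue into a single gene-level summary, then asks which
molecular pathways the combined signal concentrates in, and separately
contrasts two phenotype groups (responders vs nonresponders) on
group-mean abundances. All expression matrices are treated as log2
intensities; fold changes are differences of log2 means.

### Per-study statistics

Within a study, replicate arrays of one individual are averaged first so
each individual carries the same weight regardless of how often it was
arrayed; individuals missing either arm are excluded with a logged
warning. The default test is an unpaired two-sample comparison of
treated vs control columns, because several emulated designs have a
single donor with replicate arrays on both arms; a paired mode
(per-individual differences, one-sample t) exists for paired-eye
designs.

Small studies estimate per-gene variances poorly, so the t-test
optionally (and by default) moderates them: per-gene sample variances
s² with d residual degrees of freedom are assumed to follow a scaled
chi-square around a prior s0² with d0 degrees of freedom; (d0, s0²) are
estimated by moment matching on log s² (mean and variance matched via
digamma/trigamma identities, trigamma inverted by Newton iteration), and
the posterior variance (d0·s0² + d·s²)/(d0 + d) feeds a t statistic with
d0 + d degrees of freedom. When the observed spread of log s² is no
larger than its sampling noise, d0 is infinite and all genes share s0².
A study whose design leaves no residual degrees of freedom (one
individual per arm after averaging) reports p = 1 with a per-gene flag;
such studies contribute their LogFC with zero weight downstream, which
is the intended behavior of evidence weighting, not an error state.

Probes map to genes through a supplied table; unmapped probes are
counted, never silently dropped. When several probes measure one gene,
the record maximizing |LogFC · (−log₁₀ p)| is kept — selection only,
never editing — with exact ties broken toward the lexicographically
smallest probe id so runs are reproducible.

### Integration

For each gene measured by n ≥ k_min studies (default 4 of 5):

* weighted LogFC = Σ logFCᵢ·wᵢ / Σ wᵢ with wᵢ = −log₁₀ pᵢ;
* average weight = Σ wᵢ / n, back-transformed to the combined
  p = 10^(−average weight), i.e. the geometric mean of the pᵢ.

p-values are clamped below at 1e-300 upstream so weights stay finite.
If every pᵢ = 1 all weights vanish; the unweighted mean is used and
flagged (`used_fallback`). An alternative weighting that additionally
multiplies each study's weight by its number of individuals is available
(`IntegrationConfig.size_weighted`); the −log₁₀ p weighting is the
default because p-values already absorb study size through power, and
the size multiplier would double-count it. Differential expression uses
strict inequalities: |weighted LogFC| > 0.58 (2^0.58 ≈ 1.5-fold) and
combined p < 0.05, so a gene exactly at a cutoff is not called.

### Responder contrast

LogFC_R = log₂((A+1)/(B+1)) and LogFC_NR = log₂((C+1)/(D+1)) on
group-mean abundances; the +1 pseudocount is part of the definition (it
is what keeps zero-abundance genes finite) and is configurable only
through an expert argument. The difference LogFC_R − LogFC_NR isolates
responder-specific effects (a treatment effect common to both groups
cancels); the mean is the overall treatment effect. Changed genes are
called on |value| > 0.58 alone — this branch has no p-values.

### Overrepresentation and permutation null

The Z-score standardizes r against the hypergeometric null of drawing n
genes without replacement from a universe of N with R changed:
mean nR/N, variance n·(R/N)(1−R/N)·(N−n)/(N−1). Zero-variance cases
(R = 0 or R = N) return z = 0. The permutation null reshuffles the
changed labels over the measured universe, preserving R and every
pathway's n, and is one-sided (overrepresentation), matching the
z ≥ +1.96 rule; p = (1 + #{z* ≥ z_obs})/(n_perm + 1) with add-one
smoothing so p is never 0. Since N, R, n are fixed under permutation,
z* ≥ z_obs is evaluated as r* ≥ r_obs. The universe is the full set of
genes with data (post-filter integrated genes, or all genes of the
contrast table), not the pathway-annotated subset. No multiplicity
adjustment enters the significance rule — the rule is the joint
three-part criterion (z ≥ 1.96, permuted p < 0.05, r > 3, i.e. r ≥ 4) —
but a Benjamini–Hochberg column is emitted for transparency.

### Categories and network

Functional categorization of pathways is fundamentally a curation task;
the faithful mode therefore reads a pathway→category mapping file and
labels anything unmapped "unassigned". The automated surrogate
single-linkage clusters significant pathways on the Jaccard similarity
of their changed-gene sets (edge at ≥ 0.3 by default, clusters =
connected components, each labelled by its largest pathway's name); its
provenance is recorded in every output so the two modes cannot be
confused. The network links each gene with |LogFC| above the display
cutoff (default 0.58) to every category holding a significant pathway
that lists it as changed; a gene node's degree is its cluster
multiplicity (the node-size attribute), and categories left without
genes are dropped. Exports: GraphML with attributes, SIF topology,
and a shared-gene table (genes in ≥ 2 clusters, sorted by multiplicity).

## Synthetic data: what it emulates and what it does not

The generator mirrors the structure the pipeline assumes: five studies
with 1, 2, 3, 5 and 6 individuals (the donor counts of the emulated
study collection), triplicate arrays per individual, per-study gene
coverage drawn uniformly from 85–100%, ~30% of genes measured by two
probes (probes share the gene effect plus a fixed probe offset, so
deduplication has real work), gene baselines N(7, 1), additive Gaussian
noise on the log2 scale (default sd 0.3), and a planted effect of ±1
log2 unit in 5% of genes, concentrated into three designated pathways at
60% membership. The responder table plants a 1.5 log2-unit
responder-specific effect in 100 genes multiplicatively on
(abundance+1), so the construction is pseudocount-exact at zero noise
and abundances stay non-negative. One master seed drives everything;
each study uses a fixed-offset substream so adding a study leaves
earlier studies bit-identical. A config whose coverage would leave (in
expectation) no gene in ≥ 4 studies is rejected as infeasible.

Deliberately not modelled: array-platform artifacts (the simulation
starts at normalized intensities), RNA-seq counting noise,
between-individual biological variance components, correlated genes, and
batch effects. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under its stated assumptions,
not robustness to every pathology of real microarray data.

## Numerical and design choices

* Quantile normalization assigns each value the mean of the sorted
  columns at its rank; ties within a column receive the mean of the
  rank-means they span (the standard convention).
* QC flags samples whose median Pearson correlation to the rest falls
  below 0.8 (configurable); constant samples are flagged with an
  explicit reason. Flagging never deletes — dropping flagged samples is
  an explicit switch, keeping the automated surrogate for what is
  really a curator's judgment auditable.
* All thresholds (0.58, 0.05, 1.96, r > 3, 4-of-5) are config defaults,
  overridable and recorded in output provenance headers; numeric output
  uses six significant digits for byte-stable reruns.
* Validation problem sizes: formula fidelity on 1000 random tuples;
  permutation calibration on a 2000-gene universe with 200 random
  pathways (sizes 5–50), 1000 permutations, 20 seeds; planted-pathway
  recovery (20-gene pathway, 60% changed vs 5% background) over 50
  seeds; integration recovery on one 2000-gene five-study simulation;
  the Z-score checked against exhaustive hypergeometric enumeration for
  every N ≤ 40. These sizes make the full validation run in seconds
  while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The moderated t-test is a generic empirical-Bayes shrinkage; it
  approximates but does not replicate any specific fitting package's
  estimates (option `moderate=False` gives the textbook pooled t).
* Single-donor studies cannot contribute p-values in unpaired mode; the
  combined p over n studies still divides by n, so such studies dilute
  the average weight — a property of the combination formula itself.
* The weighted LogFC is mildly biased away from zero for true effects,
  because weights correlate with the observed effect through the
  p-value; at the default study conditions the measured bias is ~3%.
* The automated Jaccard categorization is a surrogate: cluster labels
  are pathway names, not biological category names, and a curated
  mapping should be preferred whenever one exists.
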