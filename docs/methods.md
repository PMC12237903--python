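# Methods

This note documents the models, parameter choices and numerical
conventions behind `gutnet`, and what the synthetic benchmarks do and do
not demonstrate.

## Synthetic data model

The generator emulates multi-location 16S OTU tables with a standard
compositional benchmark: per sample, log basis abundances
z ~ MVN(μ, diag(σ)·C·diag(σ)), basis abundances exp(z) closed to
proportions, library size ~ Poisson(depth_mean) (floored at 1 read), and
counts a multinomial draw of that size from the proportions. The planted
correlation matrix C is identity off the declared entries and must be
positive semi-definite (minimum eigenvalue ≥ −1e−10); invalid
specifications are rejected rather than repaired, so ground truth is
always exactly what was requested. Sites are generated independently
with sub-seeds `seed + site_index`; a site's planted structure is the
union of the study's shared pairs and its own specific pairs.

Defaults: μ = 0, σ = 1 (log-normal basis with unit log-sd, a typical
magnitude for OTU-level variation), depth_mean = 10,000 reads (a
realistic 16S library), Poisson-varying depth to exercise unequal
library sizes. Desk-scale studies in the tests use 12–50 OTUs and
40–200 samples per site; the three-location design mirrors the
ileum/cecum/feces setting with site-dependent richness available through
per-site `n_otus`.

What the generator does **not** emulate: PCR/chimera artifacts,
phylogenetic correlation between lineages and abundances, overdispersion
beyond multinomial, zero-inflation beyond what closure and depth induce,
or realistic taxonomic composition (lineages are drawn uniformly from a
small fixed vocabulary). Passing recovery tests therefore show the
inference is correct under the log-normal/multinomial compositional
model, not that it is robust to every artefact of real surveys.

A note on the clr-Pearson oracle used in tests: the centred log-ratio
correlation of a D-part composition carries an O(1/D) negative bias on
null pairs; null-centering checks use D = 30 so the bias is within the
tolerance, and planted-pair comparisons tolerate ±0.15–0.2.

## SparCC inference

Fractions are drawn per sample from Dirichlet(counts + 1); the variation
matrix uses sample variances (n−1) computed from the covariance of log
fractions. The basis system M·ω = t·1 (diagonal D−1, off-diagonal 1) is
solved with `numpy.linalg.solve`; ω is floored at 1e−10 before the
square root and correlations are clipped to [−1, 1]. The exclusion loop
(up to 10 iterations) removes the currently strongest |r| pair above
threshold 0.1 from both M and the row sums and re-solves; an OTU
accumulating ≥ D_active − 3 exclusions is dropped from the system with
its correlations set to 0. The point estimate is the elementwise median
over 50 Dirichlet resamples; all of these are the FastSpar defaults and
are exposed as parameters. At least 4 OTUs are required (the basis
system is underdetermined below) and at least 10 samples.

Bootstrap p-values permute each OTU's counts independently across
samples (destroying association, preserving marginals), re-run SparCC
with 5 inner Dirichlet resamples (recorded in the settings), and use the
two-sided (1 + exceedances)/(1 + B) convention; B defaults to 1000 in
the library, with B = 100 used throughout the desk-scale tests. Raw
p < 0.05 (strict) retains a pair for downstream analysis; no multiplicity
adjustment is applied at this stage, matching the retention rule the
network construction uses (BH adjustment is available separately).

## Stability meta-analysis

Correlations become effects via Fisher's z with se = 1/√(n−3), n being
the number of samples behind that site's SparCC run; |r| = 1 is rejected
unless explicitly clipped to ±0.9999. Cochran's Q with inverse-variance
weights is referred to χ²(k−1), k the number of sites in the comparison
(pairwise comparisons use k = 2, the all-site comparison k = 3); Q
p > 0.05 flags a pair stable. The Fisher-z standard error is exact for
Pearson correlations of bivariate normal data and approximate for SparCC
estimates (which add Dirichlet-resampling variability); the end-to-end
benchmark shows ≥ 80% of planted equal-correlation pairs are still
flagged stable. The |r|-bin summary of stable pairs uses each pair's
mean |r| across the compared sites in bins of width 0.1.

## Networks and topology

Edges require |r| > 0.5 strictly; the absolute value is used so negative
(exclusion) relationships survive thresholding, with `use_absolute=False`
available. Sign and magnitude are kept as edge attributes, but all
topology (clustering, modularity, shortest paths, efficiency) is
computed on the unweighted graph — no weighted variant is defined here.

Modules come from greedy (CNM) modularity maximisation
(`networkx.community.greedy_modularity_communities`), with module labels
ordered by smallest member for determinism. Zi is the within-module
degree z-score (population sd; 0 when a module's within-degrees are
constant); Pi = 1 − Σ_m (k_im/k_i)² with Pi = 0 for isolated nodes.
Role quadrants at Zi = 2.5, Pi = 0.62: peripheral, connector (Pi above),
module hub (Zi above), network hub (both); hubs are all non-peripheral
nodes. The source material's verbal role definitions assign connector
and network hub the same condition and leave one quadrant unnamed; the
standard four-quadrant convention is used instead and noted in output
metadata.

The degree-distribution call fits log10 P(k) against log10 k over the
observed degrees, weighting each point by its node count: every node
contributes equally, where an unweighted fit would be dominated by rare
tail degrees (each a single node) and by occasional low-degree artifact
nodes of the generators. A network is called scale-free iff the weighted
R² ≥ 0.8 and the slope ≤ −1, else random; both thresholds are
configurable, and the full histogram and cumulative distribution are
emitted so the call can be judged visually. The fit describes the
empirical slope; it is a classification heuristic, not a rigorous
power-law test.

Global efficiency is the mean inverse shortest-path length over pairs
(unreachable pairs contribute 0). Node vulnerability
V_i = (E − E_−i)/E uses the induced subgraph's own normalisation over
N−1 nodes, so removing a peripheral node can *raise* mean efficiency and
give a negative V_i; such values are reported, not clamped. Network
vulnerability is the maximum over nodes.

## Stability index and robustness

wMIS_i averages a node's signed correlations weighted by neighbour mean
relative abundance. The stability index S = Σ_{i∈core} |wMIS_i| /
n_total is a reconstruction: the upstream description names the three
ingredients (interaction strength, core-node count, total nodes) without
a formula, so the single composite above is used and all components are
also reported separately for alternative composites.

The robustness simulation removes ⌈0.5·N⌉ nodes per replicate, 10
replicates: hub-targeted removal takes all hubs first (random order),
then highest-degree non-hubs; random removal draws uniformly from
non-hubs only (hubs are never removed unless non-hubs run out, which is
flagged). wMIS is *recomputed* on the surviving subgraph — removal
severs interactions — and robustness is the retained fraction of total
|wMIS| (absolute values, so negative interactions do not cancel positive
ones; signed totals are available). Replicate vectors are compared by an
exact permutation rank-sum test (the replicate vectors are tiny and
often tied, where the asymptotic Mann-Whitney approximation is poor),
BH-corrected across sites.

On the synthetic preferential-attachment benchmark the Zi/Pi hub set is
a *majority* of nodes (most nodes are connectors), which exceeds the 50%
removal quota and collapses the targeted-vs-random contrast; the
benchmark therefore uses the degree-ranked top-10% hub set — the same
fallback the pipeline engages when role-based hubs are absent. Real
co-abundance networks have minority hub sets and use the role-based
definition.

## Location-specific calls

Criterion order follows the "or": a pair present in exactly one site is
specific there iff |r| ≥ 0.6 (inclusive); otherwise, a pair is specific
to its strongest site iff the gap between its |r| and the best |r|
anywhere else (absence scored as 0) strictly exceeds 0.6. Gaps compare
absolute values, so a strong negative edge can be specific. Exact ties
for the strongest site that would otherwise qualify are flagged
ambiguous, listed separately and excluded from counts. Calls are made on
the p < 0.05 significant catalogs; taxon-pair summaries fall back from
genus to the lowest annotated higher rank, and unmapped OTUs become
"Unclassified".

## Community statistics

Filtering keeps OTUs with prevalence and mean per-sample relative
abundance strictly above 10% and 0.01% respectively (the two cutoffs the
retention rule names); "abundance" is operationalised as the mean of
per-sample proportions, and a `strict=False` flag gives the ≥ variants.
Shannon uses the natural log; Simpson is 1 − Σp²; Chao1 is
S + F1²/(2F2), switching to the bias-corrected S + F1(F1−1)/2 only when
F2 = 0 (vegan behaviour); ACE uses the standard rare cutoff 10 via
scikit-bio. Bray-Curtis is computed on relative abundances. PCoA is
classical double-centering with negative eigenvalues reported
uncorrected (cross-checked against scikit-bio). PERMANOVA implements the
pseudo-F decomposition directly (R² is required output; the pseudo-F is
cross-checked against scikit-bio) with the (1 + exceedances)/(1 +
permutations) convention, 999 permutations by default. Group tests are
two-sided Wilcoxon rank-sum (exact for small untied samples) with BH
adjustment at FDR 0.05.

## Pipeline conventions

One global seed; each stage derives `(seed + crc32(stage_name)) % 2^31`
so stages re-run in isolation reproduce the full run (the manifest
records every sub-seed and output checksum). Tabular outputs are TSV
with 12-significant-digit floats, networks GraphML, reports JSON. A
stage failure is recorded and its dependents skipped; the run still
produces a manifest.

## Benchmark problem sizes

The test-suite and acceptance-script benchmarks use desk-scale problems
chosen to make the statistical properties measurable while keeping runs
short: SparCC recovery at 50 OTUs × 200 samples × depth 20,000 with five
planted pairs at basis correlation 0.8; graph-oracle agreement on all
142 connected graphs with ≤ 6 nodes plus 100 random graphs at 7–8;
Cochran-Q calibration on 1,000 pair-triples at n = 300; degree
classification on 500-node graphs over 10 seeds; robustness
directionality on 20 seeded 60-node preferential-attachment networks;
and end-to-end specificity recovery on three 30-OTU × 200-sample sites
over 5 seeds with bootstrap B = 100.

## Known limitations

- The stability index and wMIS definitions are reconstructions of
  verbally described quantities; outputs carry the components so other
  composites can be formed.
- Fisher-z standard errors treat SparCC estimates as Pearson
  correlations; the Q test is slightly miscalibrated for very strong
  correlations estimated with few Dirichlet resamples.
- The scale-free call is a regression heuristic, not a maximum-
  likelihood power-law test with goodness-of-fit simulation.
- Full-scale surveys (hundreds of OTUs, thousands of samples, B = 1000
  bootstraps) are supported by the same code paths but were not
  benchmarked here; SparCC cost grows roughly with
  resamples × exclusion iterations × D³.
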