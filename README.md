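# gutnet

Spatial heterogeneity analysis of gut microbial co-abundance networks.

The gut is not one habitat: the microbial community of the ileum differs
from that of the cecum and of feces, and so do the *interactions* between
taxa. `gutnet` implements the full analysis chain for asking where in the
gut a microbial co-abundance relationship holds: from OTU count tables
through compositional correlation inference, cross-location stability
testing, network construction and topological characterisation, to
calling gut-location-specific relationships. A synthetic-data generator
with planted ground truth makes every stage testable without sequencing
data.

## What it computes

**SparCC correlations.** 16S counts are compositional, so Pearson
correlations on proportions are spurious. SparCC works from the variation
matrix t_ij = Var[ln(f_i/f_j)]; with ω_i the log basis-abundance variance
of OTU i, the sparsity assumption turns the row sums of t into the linear
system M·ω = t·1 (M with diagonal D−1, off-diagonal 1) and

    r_ij = (ω_i + ω_j − t_ij) / (2 √(ω_i ω_j)).

Strongly correlated pairs are iteratively excluded and the system
re-solved; count noise is integrated out by taking the elementwise median
over Dirichlet posterior resamples of the fractions. Two-sided p-values
come from a permutation bootstrap that shuffles each OTU's counts
independently across samples. Exposed both as functions and as a
scikit-learn estimator (`SparCC(...).fit(X)` → `correlation_`,
`pvalues_`).

**Cross-location stability.** A pair significant (p < 0.05) in several
locations carries one correlation per location. Each is Fisher-z
transformed (z = atanh r, se = 1/√(n−3)); Cochran's
Q = Σ w_i (z_i − z̄)², w_i = 1/se_i², tests heterogeneity against
χ²(k−1). Pairs with Q p > 0.05 are *stable* across locations.

**Networks and topology.** Edges with |r| > 0.5 form an undirected
signed-weight network per location. The battery: node/edge counts,
average degree, clustering coefficient, Freeman degree centralization,
fast-greedy modules and Newman modularity, Guimerà–Amaral Zi/Pi node
roles (hubs = non-peripheral nodes at Zi = 2.5, Pi = 0.62), a log-log
degree-distribution fit classifying each network as random vs scale-free,
and efficiency-based vulnerability V_i = (E − E_−i)/E with the network's
vulnerability the maximum over nodes.

**Stability and robustness.** Per node, the abundance-weighted mean
interaction strength wMIS_i = Σ_j a_j r_ij / Σ_j a_j over neighbours j;
core nodes are OTUs present in every location's network; the stability
index S = Σ_core |wMIS_i| / n_total. Robustness removes 50% of nodes
(hub-targeted vs random non-hub), recomputes wMIS on the surviving
subgraph and reports the retained fraction of total |wMIS| over 10
seeded replicates, compared by exact rank-sum tests with BH correction.

**Location-specific relationships.** A relationship is specific to a
location when it exists only there with |r| ≥ 0.6, or when its |r| gap to
the best other location (absence = 0) exceeds 0.6; calls are summarised
per location, by sign, and collapsed to taxon pairs via Greengenes-style
lineages.

**Community statistics.** Prevalence/abundance OTU filtering, alpha
diversity (observed richness, Chao1, ACE, Shannon, Simpson), Bray-Curtis
distances, PCoA, PERMANOVA (pseudo-F, R², seeded permutation p) and
Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment.

## Worked example

```python
import gutnet as gn

# three gut locations with one shared and one ileum-specific planted pair
designs = [gn.SiteDesign(site, n_otus=20, n_samples=120, depth_mean=5000, sigma=1.0)
           for site in ("ileum", "cecum", "feces")]
bundle = gn.generate_multisite_study(
    designs,
    shared_pairs=[(0, 1, 0.8)],
    specific_pairs={"ileum": [(2, 3, 0.9)]},
    seed=42,
)

catalogs = {}
for k, (site, table) in enumerate(bundle.tables.items()):
    rho = gn.sparcc(table, seed=k)
    p = gn.sparcc_pvalues(table, rho, n_bootstrap=100, seed=k + 10)
    catalogs[site] = gn.significant_pairs(rho, p, table.otu_ids, site=site)
    print(f"{site}: rho(OTU_1,OTU_2) = {rho[0, 1]:.3f}, "
          f"rho(OTU_3,OTU_4) = {rho[2, 3]:.3f}, "
          f"{len(catalogs[site])} significant pairs")

stab = gn.classify_shared_pairs(catalogs, {s: 120 for s in catalogs})
summary = stab["comparisons"]["ileum|cecum|feces"]["summary"]
print(f"shared in all 3 locations: {summary['n_shared']}, "
      f"stable (Q p > 0.05): {summary['n_stable']}")

report = gn.location_specific_pairs(catalogs)
for row in report["pairs"].itertuples(index=False):
    print(f"location-specific: {row.otu_a}--{row.otu_b} in {row.site} "
          f"({row.criterion}, r = {row.r:.2f})")
```

prints

```
ileum: rho(OTU_1,OTU_2) = 0.747, rho(OTU_3,OTU_4) = 0.886, 12 significant pairs
cecum: rho(OTU_1,OTU_2) = 0.766, rho(OTU_3,OTU_4) = -0.109, 12 significant pairs
feces: rho(OTU_1,OTU_2) = 0.794, rho(OTU_3,OTU_4) = 0.052, 13 significant pairs
shared in all 3 locations: 1, stable (Q p > 0.05): 1
location-specific: OTU_3--OTU_4 in ileum (single_site, r = 0.89)
```

The pair planted with equal basis correlation 0.8 in all three locations
is recovered everywhere (estimates 0.75–0.79), survives the Cochran-Q
heterogeneity test as stable, and is not called location-specific; the
pair planted only in the ileum (0.9) is recovered there (0.89), absent
elsewhere, and called ileum-specific under the single-location criterion.

The same chain runs from the shell on TSV inputs:

```sh
gutnet simulate --sites ileum,cecum,feces --n-otus 30,60,80 --out sim/
gutnet run-all --config config.json --seed 1 --out results/
```

where `config.json` holds the input paths and any stage parameters
(see `gutnet.PipelineConfig` for the schema and defaults).

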