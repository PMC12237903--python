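"""Synthetic multi-site compositional count data with planted correlations.

Real 16S surveys of the pig gut sample three locations (ileum, cecum,
feces) whose retained OTU richness differs strongly; sequencing yields
compositional counts.  This module emulates that setting with the standard
log-normal + multinomial benchmark: per sample, basis abundances are
``exp(z)`` with ``z`` multivariate normal, the correlation structure of
``z`` carries the *planted* (ground-truth) OTU-OTU associations, and reads
are a multinomial draw of Poisson-distributed depth from the closed
(renormalised) basis.  Planted pairs can be shared across all sites or
site-specific, giving downstream recovery tests a known answer key.

Toy graph fixtures for the topology oracles live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import OtuTable, TaxonomyMap

PSD_TOL = -1e-10


@dataclass
class CorrSpec:
    """Planted basis-correlation structure.

    ``pairs`` is a list of ``(i, j, rho)`` with distinct indices; ``blocks``
    optionally adds index sets with a uniform within-block correlation.
    The implied correlation matrix must be positive semi-definite.
    """

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    blocks: list[tuple[list[int], float]] = field(default_factory=list)

    def matrix(self, n_otus: int) -> np.ndarray:
        c = np.eye(n_otus)
        for members, rho in self.blocks:
            members = list(members)
            for a in members:
                for b in members:
                    if a != b:
                        c[a, b] = rho
        for i, j, rho in self.pairs:
            if i == j:
                raise ValueError(f"pair indices must be distinct, got ({i}, {j})")
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho must be in [-1, 1], got {rho}")
            if not (0 <= i < n_otus and 0 <= j < n_otus):
                raise ValueError(f"pair ({i}, {j}) out of range for {n_otus} OTUs")
            c[i, j] = c[j, i] = rho
        self.validate_psd(c)
        return c

    @staticmethod
    def validate_psd(c: np.ndarray) -> None:
        eigmin = float(np.linalg.eigvalsh(c)[0])
        if eigmin < PSD_TOL:
            raise ValueError(
                f"correlation spec is not positive semi-definite (min eigenvalue {eigmin:.3e})"
            )


@dataclass
class SiteDesign:
    """One gut location's simulation design."""

    site_name: str
    n_otus: int
    n_samples: int
    depth_mean: float = 10_000.0
    mu: np.ndarray | float = 0.0
    sigma: np.ndarray | float = 1.0
    corr_spec: CorrSpec = field(default_factory=CorrSpec)

    def __post_init__(self):
        if self.n_otus < 4:
            raise ValueError("n_otus must be >= 4 (basis-variance system is degenerate below)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.depth_mean < 100:
            raise ValueError("depth_mean must be >= 100")
        self.mu = np.broadcast_to(np.asarray(self.mu, dtype=float), (self.n_otus,)).copy()
        self.sigma = np.broadcast_to(np.asarray(self.sigma, dtype=float), (self.n_otus,)).copy()
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")


@dataclass
class StudyBundle:
    """A multi-site synthetic study plus its planted ground truth."""

    tables: dict[str, OtuTable]
    taxonomy: TaxonomyMap
    truth: dict[str, CorrSpec]
    shared_pairs: list[tuple[int, int, float]]
    specific_pairs: dict[str, list[tuple[int, int, float]]]

    @property
    def sites(self) -> list[str]:
        return list(self.tables)


def generate_basis_counts(design: SiteDesign, seed: int) -> OtuTable:
    """Simulate one site's OTU count table.

    Per sample: ``z ~ MVN(mu, diag(sigma) C diag(sigma))`` with ``C`` the
    planted correlation matrix; basis abundances ``exp(z)`` are closed to
    proportions; the library size is Poisson(``depth_mean``) and counts a
    multinomial draw from the proportions.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    corr = design.corr_spec.matrix(design.n_otus)
    cov = corr * np.outer(design.sigma, design.sigma)
    z = rng.multivariate_normal(design.mu, cov, size=design.n_samples, method="svd")
    basis = np.exp(z)  # samples x OTUs
    props = basis / basis.sum(axis=1, keepdims=True)
    depths = rng.poisson(design.depth_mean, size=design.n_samples)
    depths = np.maximum(depths, 1)  # a zero-read sample is not a usable library
    counts = np.empty((design.n_samples, design.n_otus), dtype=np.int64)
    for s in range(design.n_samples):
        counts[s] = rng.multinomial(depths[s], props[s])
    otu_ids = [f"OTU_{i + 1}" for i in range(design.n_otus)]
    sample_ids = [f"{design.site_name}_S{j + 1}" for j in range(design.n_samples)]
    sites = [design.site_name] * design.n_samples
    return OtuTable(counts.T, otu_ids=otu_ids, sample_ids=sample_ids, sites=sites)


def generate_multisite_study(
    designs: list[SiteDesign],
    shared_pairs: list[tuple[int, int, float]] | None = None,
    specific_pairs: dict[str, list[tuple[int, int, float]]] | None = None,
    seed: int = 0,
    taxonomy_vocab_seed_offset: int = 1000,
) -> StudyBundle:
    """Generate a multi-site study with shared and site-specific planted pairs.

    Each site's correlation spec is the union of ``shared_pairs`` and that
    site's entry in ``specific_pairs``; tables are simulated independently
    per site with sub-seeds ``seed + site_index``.
    """
    if len(designs) < 2:
        raise ValueError("need at least 2 site designs")
    shared_pairs = list(shared_pairs or [])
    specific_pairs = {k: list(v) for k, v in (specific_pairs or {}).items()}
    names = [d.site_name for d in designs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate site names")
    for site in specific_pairs:
        if site not in names:
            raise ValueError(f"specific pairs given for unknown site {site!r}")

    tables: dict[str, OtuTable] = {}
    truth: dict[str, CorrSpec] = {}
    for k, design in enumerate(designs):
        site = design.site_name
        pairs = shared_pairs + specific_pairs.get(site, [])
        for i, j, _ in pairs:
            if not (0 <= i < design.n_otus and 0 <= j < design.n_otus):
                raise ValueError(
                    f"pair ({i}, {j}) out of range for site {site!r} with {design.n_otus} OTUs"
                )
        spec = CorrSpec(pairs=pairs, blocks=list(design.corr_spec.blocks))
        design = SiteDesign(
            site_name=site,
            n_otus=design.n_otus,
            n_samples=design.n_samples,
            depth_mean=design.depth_mean,
            mu=design.mu,
            sigma=design.sigma,
            corr_spec=spec,
        )
        tables[site] = generate_basis_counts(design, seed=seed + k)
        truth[site] = spec
    n_otus_max = max(d.n_otus for d in designs)
    taxonomy = generate_taxonomy(n_otus_max, seed=seed + taxonomy_vocab_seed_offset)
    return StudyBundle(
        tables=tables,
        taxonomy=taxonomy,
        truth=truth,
        shared_pairs=shared_pairs,
        specific_pairs={s: specific_pairs.get(s, []) for s in names},
    )


def make_toy_graph(kind: str, params: dict | None = None, seed: int = 0) -> nx.Graph:
    """Small fixture graphs with unit positive edge weights.

    Kinds: ``path``, ``star``, ``triangle``, ``two_cliques`` (two K_c plus
    one bridge), ``erdos_renyi``, ``preferential_attachment``.
    """
    params = dict(params or {})
    if kind == "triangle":
        g = nx.complete_graph(3)
    elif kind == "path":
        n = int(params.get("n", 3))
        _check_n(n)
        g = nx.path_graph(n)
    elif kind == "star":
        n = int(params.get("n", 5))
        _check_n(n)
        g = nx.star_graph(n - 1)  # networkx star_graph(k) has k+1 nodes
    elif kind == "two_cliques":
        c = int(params.get("clique_size", 5))
        _check_n(c)
        g = nx.disjoint_union(nx.complete_graph(c), nx.complete_graph(c))
        g.add_edge(0, c)  # the bridge
    elif kind == "erdos_renyi":
        n = int(params.get("n", 100))
        _check_n(n)
        g = nx.gnp_random_graph(n, float(params.get("p", 0.05)), seed=seed)
    elif kind == "preferential_attachment":
        n = int(params.get("n", 100))
        _check_n(n)
        g = nx.barabasi_albert_graph(n, int(params.get("m", 3)), seed=seed)
    else:
        raise ValueError(f"unknown toy graph kind {kind!r}")
    nx.set_edge_attributes(g, 1.0, "weight")
    nx.set_edge_attributes(g, 1.0, "r")
    return g


def _check_n(n: int) -> None:
    if n < 2:
        raise ValueError("graph size must be >= 2")


# Small fixed vocabulary; genera include taxa prominent in pig-gut surveys.
_TAXA = [
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "S24-7", ""),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", ""),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Oscillospira"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Escherichia"),
    ("Bacteria", "Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Treponema"),
]

GENUS_VOCABULARY = sorted({t[5] for t in _TAXA if t[5]})


def generate_taxonomy(n_otus: int, seed: int = 0) -> TaxonomyMap:
    """Assign each OTU a Greengenes-style 7-rank lineage from a fixed vocabulary."""
    if n_otus < 1:
        raise ValueError("n_otus must be >= 1")
    rng = np.random.default_rng(seed)
    choices = rng.integers(0, len(_TAXA), size=n_otus)
    lineages = {}
    for i, c in enumerate(choices):
        k, p, cl, o, f, g = _TAXA[c]
        lineages[f"OTU_{i + 1}"] = (
            f"k__{k}; p__{p}; c__{cl}; o__{o}; f__{f}; g__{g}; s__"
        )
    return TaxonomyMap(lineages)
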