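"""End-to-end pipeline: configuration, orchestration and run manifest.

Per site: filter -> alpha diversity -> SparCC (+ bootstrap p) ->
significant pairs -> network -> topology -> wMIS.  Across sites:
beta diversity (Bray-Curtis / PCoA / PERMANOVA), shared-pair stability,
core nodes, stability index, robustness simulation and location-specific
calls.  Every stage gets a sub-seed derived from the global seed and the
stage name, so stages are independently re-runnable; the manifest records
config, seeds, per-stage timing and output checksums.
"""

from __future__ import annotations

import hashlib
import time
import traceback
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import community, meta, robustness, sparcc, specific, topology
from . import io as gio
from .datatypes import OtuTable, TaxonomyMap

__version__ = "0.1.0"

_RANGES = {
    "prevalence_min": (0.0, 1.0),
    "abundance_min": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "alpha_stable": (0.0, 1.0),
    "r_min": (0.0, 1.0),
    "zi_cut": (0.0, 100.0),
    "pi_cut": (0.0, 1.0),
    "delta_min": (0.0, 2.0),
    "single_site_min": (0.0, 1.0),
    "removal_fraction": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """All stage parameters plus input paths, seed and output directory."""

    tables: dict[str, str] = field(default_factory=dict)
    taxonomy: str | None = None
    metadata: str | None = None
    out_dir: str = "gutnet_out"
    seed: int = 0
    # filtering
    prevalence_min: float = 0.10
    abundance_min: float = 1e-4
    strict_filter: bool = True
    # SparCC
    n_dirichlet: int = 50
    n_exclusion_iters: int = 10
    exclusion_threshold: float = 0.1
    n_bootstrap: int = 100
    bootstrap_dirichlet: int = 5
    alpha: float = 0.05
    # meta-stability
    alpha_stable: float = 0.05
    # network
    r_min: float = 0.5
    use_absolute: bool = True
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    # robustness
    removal_fraction: float = 0.5
    replicates: int = 10
    # location specificity
    delta_min: float = 0.6
    single_site_min: float = 0.6
    # beta diversity
    n_permutations: int = 999

    def __post_init__(self):
        for name, (lo, hi) in _RANGES.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name} = {val} outside [{lo}, {hi}]")
        for name in ("n_dirichlet", "n_exclusion_iters", "n_bootstrap",
                     "bootstrap_dirichlet", "replicates", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(gio.read_json(path))


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage sub-seed: global seed offset by a stage-name hash."""
    return (seed + zlib.crc32(stage.encode())) % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest(dict):
    """Plain dict of run metadata; serialised as JSON."""


def run_pipeline(
    config: PipelineConfig,
    tables: dict[str, OtuTable] | None = None,
    taxonomy: TaxonomyMap | None = None,
) -> RunManifest:
    """Execute the full per-site and cross-site analysis.

    ``tables``/``taxonomy`` may be passed in-memory; otherwise they are
    read from the config paths.  A stage failure is recorded in the
    manifest and dependent stages are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        stages={},
        outputs={},
    )

    def _record(path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _checksum(path)

    def _run(stage: str, fn):
        t0 = time.perf_counter()
        entry = {"seed": stage_seed(config.seed, stage)}
        try:
            fn(entry["seed"])
            entry["status"] = "ok"
        except Exception as exc:  # recorded, downstream skipped by caller checks
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["traceback"] = traceback.format_exc(limit=3)
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = entry
        return entry["status"] == "ok"

    if tables is None:
        tables = {site: gio.read_otu_table(path) for site, path in config.tables.items()}
    if taxonomy is None and config.taxonomy:
        taxonomy = gio.read_taxonomy(config.taxonomy)
    sites = list(tables)
    if len(sites) < 2:
        raise ValueError("need >= 2 sites for the cross-site stages")

    state: dict = {"filtered": {}, "catalogs": {}, "networks": {}, "abund": {}, "roles": {}}

    for site in sites:
        sdir = out / site
        sdir.mkdir(exist_ok=True)
        table = tables[site]

        def _filter(seed, site=site, table=table, sdir=sdir):
            filtered = community.filter_otus(
                table, config.prevalence_min, config.abundance_min, strict=config.strict_filter
            )
            state["filtered"][site] = filtered
            state["abund"][site] = filtered.mean_relative_abundance()
            gio.write_otu_table(filtered, sdir / "filtered_otu_table.tsv")
            _record(sdir / "filtered_otu_table.tsv")

        if not _run(f"{site}/filter", _filter):
            continue

        def _diversity(seed, site=site, sdir=sdir):
            adiv = community.alpha_diversity(state["filtered"][site])
            adiv.to_csv(sdir / "alpha_diversity.tsv", sep="\t", float_format="%.12g")
            _record(sdir / "alpha_diversity.tsv")

        _run(f"{site}/diversity", _diversity)

        def _sparcc(seed, site=site, sdir=sdir):
            filtered = state["filtered"][site]
            rho = sparcc.sparcc(
                filtered,
                n_dirichlet=config.n_dirichlet,
                n_exclusion_iters=config.n_exclusion_iters,
                exclusion_threshold=config.exclusion_threshold,
                seed=seed,
            )
            p = sparcc.sparcc_pvalues(
                filtered, rho,
                n_bootstrap=config.n_bootstrap,
                seed=seed + 1,
                n_dirichlet=config.bootstrap_dirichlet,
                n_exclusion_iters=config.n_exclusion_iters,
                exclusion_threshold=config.exclusion_threshold,
            )
            catalog = sparcc.significant_pairs(rho, p, filtered.otu_ids,
                                               alpha=config.alpha, site=site)
            state["catalogs"][site] = catalog
            gio.write_matrix(rho, filtered.otu_ids, sdir / "sparcc_rho.tsv")
            gio.write_matrix(p, filtered.otu_ids, sdir / "sparcc_p.tsv")
            gio.write_edge_catalog(catalog, sdir / "edges.tsv")
            for name in ("sparcc_rho.tsv", "sparcc_p.tsv", "edges.tsv"):
                _record(sdir / name)

        if not _run(f"{site}/sparcc", _sparcc):
            continue

        def _network(seed, site=site, sdir=sdir):
            g = topology.build_network(
                state["catalogs"][site], r_min=config.r_min,
                use_absolute=config.use_absolute, abundances=state["abund"][site]
            )
            state["networks"][site] = g
            if g.number_of_nodes() == 0:
                return
            partition, n_modules, q = topology.detect_modules(g)
            roles = topology.zi_pi(g, partition, zi_cut=config.zi_cut, pi_cut=config.pi_cut)
            state["roles"][site] = roles
            metrics = topology.global_metrics(g, partition)
            metrics.update(topology.degree_stats(g))
            metrics.pop("degrees")
            try:
                fit = topology.fit_degree_distribution(g)
                metrics.update(degree_fit_slope=fit.slope, degree_fit_r2=fit.r_squared,
                               degree_classification=fit.classification)
            except ValueError:
                metrics["degree_classification"] = "too_small"
            vul = topology.vulnerability(g)
            metrics.update(efficiency=vul["efficiency"],
                           network_vulnerability=vul["network_vulnerability"])
            for node, v in vul["node_vulnerability"].items():
                g.nodes[node]["vulnerability"] = v
            for node in g.nodes:
                g.nodes[node]["module"] = int(partition[node])
                g.nodes[node]["Zi"] = float(roles.loc[node, "Zi"])
                g.nodes[node]["Pi"] = float(roles.loc[node, "Pi"])
                g.nodes[node]["role"] = roles.loc[node, "role"]
            w = robustness.wmis(g, state["abund"][site])
            for node, val in w.items():
                g.nodes[node]["wMIS"] = float(val)
            w.to_csv(sdir / "wmis.tsv", sep="\t", float_format="%.12g")
            gio.write_graphml(g, sdir / "network.graphml")
            gio.write_json(metrics, sdir / "topology.json")
            roles.to_csv(sdir / "node_roles.tsv", sep="\t", float_format="%.12g")
            for name in ("wmis.tsv", "network.graphml", "topology.json", "node_roles.tsv"):
                _record(sdir / name)

        _run(f"{site}/network", _network)

    cdir = out / "cross"
    cdir.mkdir(exist_ok=True)

    def _beta(seed):
        filt = state["filtered"]
        if len(filt) < 2:
            raise RuntimeError("fewer than 2 sites survived filtering")
        all_otus = sorted(set().union(*[t.otu_ids for t in filt.values()]))
        frames, labels = [], []
        for site, t in filt.items():
            frames.append(t.df.reindex(all_otus, fill_value=0))
            labels += [site] * t.n_samples
        combined = OtuTable(pd.concat(frames, axis=1), sites=labels)
        dist = community.bray_curtis(combined)
        coords, eigvals = community.pcoa(dist, k=2)
        res = community.permanova(dist, labels, n_permutations=config.n_permutations, seed=seed)
        coords.to_csv(cdir / "pcoa.tsv", sep="\t", float_format="%.12g")
        gio.write_json(res, cdir / "permanova.json")
        _record(cdir / "pcoa.tsv")
        _record(cdir / "permanova.json")

    _run("cross/beta", _beta)

    def _stability_pairs(seed):
        catalogs = state["catalogs"]
        if len(catalogs) < 2:
            raise RuntimeError("fewer than 2 site catalogs available")
        sizes = {s: state["filtered"][s].n_samples for s in catalogs}
        report = meta.classify_shared_pairs(catalogs, sizes, alpha_stable=config.alpha_stable)
        state["stability_report"] = report
        summary = {k: v["summary"] for k, v in report["comparisons"].items()}
        gio.write_json(summary, cdir / "shared_pairs_summary.json")
        _record(cdir / "shared_pairs_summary.json")
        for key, comp in report["comparisons"].items():
            fname = cdir / f"shared_pairs_{key.replace('|', '_')}.tsv"
            comp["pairs"].to_csv(fname, sep="\t", index=False, float_format="%.12g")
            _record(fname)

    _run("cross/stability_pairs", _stability_pairs)

    def _stability(seed):
        nets = {s: g for s, g in state["networks"].items() if g.number_of_nodes() > 0}
        if len(nets) < 2:
            raise RuntimeError("fewer than 2 non-empty networks")
        core = robustness.core_nodes(nets)
        reports = {}
        for site, g in nets.items():
            rep = robustness.network_stability(g, state["abund"][site], core)
            rep.pop("wmis")
            reports[site] = rep
        state["core"] = core
        gio.write_json(dict(core_nodes=sorted(core), per_site=reports),
                       cdir / "stability.json")
        _record(cdir / "stability.json")

    _run("cross/stability", _stability)

    def _robustness(seed):
        results = {}
        for site, g in state["networks"].items():
            if g.number_of_nodes() < 4 or site not in state["roles"]:
                continue
            hubs, _ = robustness.classify_hubs_for_removal(state["roles"][site])
            if not hubs:  # fall back to top-degree quota as the targeted set
                degs = sorted(g.degree, key=lambda kv: (-kv[1], kv[0]))
                hubs = {v for v, _ in degs[: max(1, g.number_of_nodes() // 10)]}
            results[site] = {}
            for strategy in ("node_hub", "node_random"):
                results[site][strategy] = robustness.robustness_sim(
                    g, state["abund"][site], strategy, hubs=hubs,
                    fraction=config.removal_fraction,
                    replicates=config.replicates, seed=seed,
                )
        for site, res in results.items():
            if {"node_hub", "node_random"} <= set(res):
                res["test"] = robustness.compare_robustness(res["node_hub"], res["node_random"])
        gio.write_json(results, cdir / "robustness.json")
        _record(cdir / "robustness.json")

    _run("cross/robustness", _robustness)

    def _specific(seed):
        catalogs = state["catalogs"]
        if len(catalogs) < 2:
            raise RuntimeError("fewer than 2 site catalogs available")
        report = specific.location_specific_pairs(
            catalogs, delta_min=config.delta_min, single_site_min=config.single_site_min
        )
        report["pairs"].to_csv(cdir / "specific_pairs.tsv", sep="\t",
                               index=False, float_format="%.12g")
        gio.write_json(dict(summary=report["summary"], n_specific=report["n_specific"]),
                       cdir / "specific_summary.json")
        _record(cdir / "specific_pairs.tsv")
        _record(cdir / "specific_summary.json")
        if taxonomy is not None:
            tax = specific.taxon_level_summary(report, taxonomy)
            tax.to_csv(cdir / "taxon_pairs.tsv", sep="\t", index=False)
            _record(cdir / "taxon_pairs.tsv")

    _run("cross/specific", _specific)

    gio.write_json(manifest, out / "manifest.json")
    return manifest
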