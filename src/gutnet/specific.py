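"""Gut-location-specific co-abundance relationship calling.

A relationship (unordered OTU pair drawn from the per-site significant
catalogs) is location-specific when either

1. it is present in exactly one location with |r| >= 0.6
   (``single_site`` criterion, checked first), or
2. the gap between its strongest |r| and the best |r| anywhere else
   (absence scoring as 0) exceeds 0.6 (``delta_r`` criterion), assigning
   it to the strongest site.

Ties for the strongest site that would otherwise qualify are flagged
ambiguous, listed separately and excluded from the counts.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import TaxonomyMap


def location_specific_pairs(
    catalogs: dict[str, pd.DataFrame],
    delta_min: float = 0.6,
    single_site_min: float = 0.6,
) -> dict:
    """Call location-specific relationships across site edge catalogs.

    Returns a dict with ``pairs`` (one row per specific relationship:
    OTUs, site, criterion, per-site r, sign), ``ambiguous`` (tied argmax),
    and a per-site summary of counts, percentages and sign split.
    """
    if len(catalogs) < 2:
        raise ValueError("need >= 2 site catalogs")
    sites = list(catalogs)
    r_by_pair: dict[tuple[str, str], dict[str, float]] = {}
    for site, cat in catalogs.items():
        for row in cat.itertuples(index=False):
            key = (str(row.otu_a), str(row.otu_b))
            r_by_pair.setdefault(key, {})[site] = float(row.r)

    rows, ambiguous = [], []
    for (otu_a, otu_b), site_r in sorted(r_by_pair.items()):
        present = list(site_r)
        base = dict(otu_a=otu_a, otu_b=otu_b)
        for s in sites:
            base[f"r_{s}"] = site_r.get(s)
        if len(present) == 1:
            site = present[0]
            r = site_r[site]
            if abs(r) >= single_site_min:
                rows.append(dict(base, site=site, criterion="single_site", r=r,
                                 sign="positive" if r > 0 else "negative"))
            continue
        # criterion 1: |r| gap to the best of the other sites (absence = 0)
        abs_r = {s: abs(site_r.get(s, 0.0)) for s in sites}
        top = max(abs_r.values())
        tied = [s for s in sites if abs_r[s] == top]
        others = [abs_r[s] for s in sites if s not in tied]
        second = max(others) if others else 0.0
        if len(tied) > 1:
            if top - second > delta_min:
                ambiguous.append(dict(base, tied_sites=tied, delta=top - second))
            continue
        site = tied[0]
        rest = max(v for s, v in abs_r.items() if s != site)
        if top - rest > delta_min:
            r = site_r[site]
            rows.append(dict(base, site=site, criterion="delta_r", r=r,
                             sign="positive" if r > 0 else "negative"))

    pairs = pd.DataFrame(rows)
    summary = {}
    total = len(pairs)
    for s in sites:
        sub = pairs[pairs["site"] == s] if total else pairs
        n = len(sub)
        summary[s] = dict(
            count=n,
            pct=(100.0 * n / total) if total else 0.0,
            positive=int((sub["sign"] == "positive").sum()) if n else 0,
            negative=int((sub["sign"] == "negative").sum()) if n else 0,
        )
    return dict(
        pairs=pairs,
        ambiguous=pd.DataFrame(ambiguous),
        summary=summary,
        n_specific=total,
    )


def taxon_level_summary(
    report: dict | pd.DataFrame,
    taxonomy: TaxonomyMap,
    rank: str = "genus",
) -> pd.DataFrame:
    """Collapse specific relationships to unordered taxon pairs at ``rank``.

    OTUs without an annotation at the requested rank fall back to the
    lowest annotated rank above it (mirroring labels that mix genus,
    family and order names); unmapped OTUs become "Unclassified".  Counts
    keep the positive/negative split and flag same-taxon pairs.
    """
    pairs = report["pairs"] if isinstance(report, dict) else report
    if len(pairs) == 0:
        return pd.DataFrame(columns=["taxon_a", "taxon_b", "site", "same_taxon",
                                     "count", "positive", "negative"])
    rows = []
    for row in pairs.itertuples(index=False):
        ta = taxonomy.taxon(row.otu_a, rank=rank)
        tb = taxonomy.taxon(row.otu_b, rank=rank)
        ta, tb = sorted((ta, tb))
        rows.append(dict(taxon_a=ta, taxon_b=tb, site=row.site,
                         positive=int(row.sign == "positive"),
                         negative=int(row.sign == "negative")))
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["taxon_a", "taxon_b", "site"], as_index=False)
        .agg(count=("positive", "size"), positive=("positive", "sum"),
             negative=("negative", "sum"))
    )
    out["same_taxon"] = out["taxon_a"] == out["taxon_b"]
    return out[["taxon_a", "taxon_b", "site", "same_taxon", "count", "positive", "negative"]]
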