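"""Cross-site stability of co-abundance pairs via Cochran-Q meta-analysis.

A pair detected in several gut locations carries one correlation per
location.  Each correlation is Fisher-z transformed (z = atanh r,
se = 1/sqrt(n−3)), the effects are pooled with inverse-variance weights,
and Cochran's Q = sum w_i (z_i − z_pooled)² tests heterogeneity against a
chi-square with k−1 degrees of freedom.  Pairs whose Q p-value exceeds
0.05 are flagged *stable* across locations (homogeneous effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EffectEstimate:
    z: float
    se: float
    n: int
    site: str = ""


@dataclass
class QResult:
    Q: float
    df: int
    p_value: float
    pooled_z: float


def fisher_z(r: float, n: int, site: str = "", clip: bool = False) -> EffectEstimate:
    """Fisher z transform of a correlation with se = 1/sqrt(n−3).

    |r| = 1 is rejected (infinite z) unless ``clip`` pre-clips to ±0.9999.
    """
    if n <= 3:
        raise ValueError("need n > 3 for a finite standard error")
    if abs(r) >= 1.0:
        if not clip:
            raise ValueError(f"|r| = {abs(r)} >= 1 gives an infinite Fisher z; pass clip=True")
        r = float(np.clip(r, -0.9999, 0.9999))
    return EffectEstimate(z=float(np.arctanh(r)), se=1.0 / np.sqrt(n - 3), n=n, site=site)


def cochran_q(effects: list[EffectEstimate]) -> QResult:
    """Inverse-variance Cochran-Q heterogeneity test across effects."""
    if len(effects) < 2:
        raise ValueError("need >= 2 effects")
    z = np.array([e.z for e in effects])
    se = np.array([e.se for e in effects])
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = float((w * z).sum() / w.sum())
    q = float((w * (z - pooled) ** 2).sum())
    df = len(effects) - 1
    p = float(stats.chi2.sf(q, df))
    return QResult(Q=q, df=df, p_value=p, pooled_z=pooled)


def _pair_key(df: pd.DataFrame) -> pd.Series:
    return df["otu_a"].astype(str) + "\t" + df["otu_b"].astype(str)


def classify_shared_pairs(
    catalogs: dict[str, pd.DataFrame],
    sample_sizes: dict[str, int],
    alpha_stable: float = 0.05,
) -> dict:
    """Shared-pair intersections and their Cochran-Q stability.

    For every pairwise site combination and for the all-site intersection,
    lists pairs present in all catalogs of the comparison, runs the
    Fisher-z / Cochran-Q test per pair (k = number of sites compared),
    and flags pairs stable when the Q p-value exceeds ``alpha_stable``.

    Returns a dict with a ``pairs`` DataFrame per comparison plus count,
    stable-count/percentage summaries and, for stable pairs, the |r|
    distribution in bins of width 0.1.
    """
    if len(catalogs) < 2:
        raise ValueError("need >= 2 site catalogs")
    sites = list(catalogs)
    indexed = {}
    for s in sites:
        df = catalogs[s].copy()
        df["_key"] = _pair_key(df)
        indexed[s] = df.set_index("_key")

    comparisons = [tuple(sites[i] for i in c) for c in _combos(len(sites))]
    report: dict = {"comparisons": {}}
    for combo in comparisons:
        keys = set(indexed[combo[0]].index)
        for s in combo[1:]:
            keys &= set(indexed[s].index)
        rows = []
        for key in sorted(keys):
            otu_a, otu_b = key.split("\t")
            effects = [
                fisher_z(float(indexed[s].loc[key, "r"]), sample_sizes[s], site=s, clip=True)
                for s in combo
            ]
            qr = cochran_q(effects)
            row = dict(otu_a=otu_a, otu_b=otu_b, Q=qr.Q, df=qr.df,
                       p_value=qr.p_value, pooled_z=qr.pooled_z,
                       stable=qr.p_value > alpha_stable)
            for s in combo:
                row[f"r_{s}"] = float(indexed[s].loc[key, "r"])
            rows.append(row)
        pairs = pd.DataFrame(rows)
        n_shared = len(pairs)
        n_stable = int(pairs["stable"].sum()) if n_shared else 0
        summary = dict(
            sites=list(combo),
            n_shared=n_shared,
            n_stable=n_stable,
            pct_stable=(100.0 * n_stable / n_shared) if n_shared else 0.0,
        )
        if n_stable:
            stable_r = pairs.loc[pairs["stable"], [f"r_{s}" for s in combo]].abs().mean(axis=1)
            bins = np.arange(0.0, 1.1, 0.1)
            hist, _ = np.histogram(np.clip(stable_r, 0, 1 - 1e-12), bins=bins)
            summary["abs_r_bins"] = {
                f"{bins[i]:.1f}-{bins[i + 1]:.1f}": dict(
                    count=int(hist[i]), pct=100.0 * hist[i] / n_stable
                )
                for i in range(len(hist))
                if hist[i] > 0
            }
        report["comparisons"]["|".join(combo)] = dict(summary=summary, pairs=pairs)
    return report


def _combos(k: int):
    """All site-index combinations of size >= 2: pairwise plus the full set."""
    out = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if k > 2:
        out.append(tuple(range(k)))
    return out
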