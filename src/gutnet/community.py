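"""Community-level statistics: OTU filtering, alpha diversity,
Bray-Curtis/PCoA ordination, PERMANOVA and Wilcoxon-BH group tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import ace as _skbio_ace
from statsmodels.stats.multitest import multipletests

from .datatypes import OtuTable


def filter_otus(
    table: OtuTable,
    prevalence_min: float = 0.10,
    abundance_min: float = 1e-4,
    strict: bool = True,
) -> OtuTable:
    """Keep OTUs by prevalence and mean relative abundance.

    An OTU is retained when its prevalence (fraction of samples with a
    positive count) and its mean per-sample relative abundance both exceed
    the cutoffs — strictly when ``strict`` (default), else >=.  Samples
    are untouched and OTU order preserved.
    """
    prevalence = (table.df > 0).mean(axis=1)
    mean_abund = table.mean_relative_abundance()
    if strict:
        keep = (prevalence > prevalence_min) & (mean_abund > abundance_min)
    else:
        keep = (prevalence >= prevalence_min) & (mean_abund >= abundance_min)
    if not keep.any():
        warnings.warn("no OTUs pass the prevalence/abundance filter")
    return OtuTable(table.df.loc[keep], sites=table.sites)


def _chao1(counts: np.ndarray) -> float:
    """Chao1: S + F1^2/(2 F2) when doubletons exist, else the
    bias-corrected S + F1(F1−1)/2 (vegan behaviour)."""
    s_obs = int(np.count_nonzero(counts))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, ACE, Shannon (natural log) and
    Simpson (1 − sum p_i^2) indices.

    Zero-total samples are reported as missing with a warning.
    """
    rows = {}
    for sample in table.sample_ids:
        counts = table.df[sample].to_numpy()
        total = counts.sum()
        if total == 0:
            warnings.warn(f"sample {sample!r} has zero total count; diversity undefined")
            rows[sample] = dict.fromkeys(
                ["observed_species", "chao1", "ace", "shannon", "simpson"], np.nan
            )
            continue
        p = counts[counts > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        pos = counts[counts > 0].astype(int)
        try:
            ace_val = float(_skbio_ace(pos, rare_threshold=10))
        except Exception:  # e.g. every taxon is a singleton
            ace_val = np.nan
        rows[sample] = dict(
            observed_species=int(np.count_nonzero(counts)),
            chao1=_chao1(counts),
            ace=ace_val,
            shannon=shannon,
            simpson=simpson,
        )
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]


def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Bray-Curtis distances on per-sample relative abundances."""
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    rel = table.relative_abundance().to_numpy().T  # samples x OTUs; rejects zero-total
    d = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def pcoa(dist: pd.DataFrame | np.ndarray, k: int = 2):
    """Classical (metric) multidimensional scaling.

    Double-centres −D²/2, eigendecomposes, and scales eigenvectors by the
    square root of the top-k positive eigenvalues.  Negative eigenvalues
    are reported unmodified; if fewer than ``k`` positive eigenvalues
    exist, fewer axes are returned with a warning.

    Returns ``(coordinates, eigenvalues)``: a DataFrame of sample
    coordinates and the full eigenvalue vector (descending).
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        ids = [f"S{j + 1}" for j in range(d.shape[0])]
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    n_pos = int(np.sum(eigvals > 1e-12))
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {k_eff} axes")
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    cols = [f"PCo{i + 1}" for i in range(k_eff)]
    return pd.DataFrame(coords, index=ids, columns=cols), eigvals


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> dict:
    """One-way PERMANOVA on a distance matrix.

    SS_total = (1/n) sum_{i<j} d_ij²; SS_within pools (1/n_g) sums within
    each group; pseudo-F = (SS_between/(g−1)) / (SS_within/(n−g));
    R² = SS_between/SS_total.  The p-value uses the (1 + exceedances) /
    (1 + permutations) convention under seeded label shuffling.
    """
    if isinstance(dist, pd.DataFrame):
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
    groups = np.asarray(list(groups))
    n = d.shape[0]
    if len(groups) != n:
        raise ValueError("group labels must match distance matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    g = len(labels)
    if g < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    d2 = d**2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n

    def _f_stat(lbls) -> tuple[float, float]:
        ss_within = 0.0
        for lab in labels:
            mask = lbls == lab
            ng = int(mask.sum())
            sub = d2[np.ix_(mask, mask)]
            ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf, ss_between
        f = (ss_between / (g - 1)) / (ss_within / (n - g))
        return f, ss_between

    f_obs, ss_between = _f_stat(groups)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = _f_stat(rng.permutation(groups))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return dict(
        pseudo_F=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
    )


def wilcoxon_bh(
    values_by_group: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment.

    ``comparisons`` defaults to all unordered group pairs; the BH family
    is the supplied comparison list.  Returns a DataFrame with the U
    statistic, raw p, BH-adjusted p and a significance flag at FDR 0.05.
    """
    names = list(values_by_group)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in comparisons:
        x = np.asarray(values_by_group[a], dtype=float)
        y = np.asarray(values_by_group[b], dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need >= 2 observations per group")
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = np.nan, 1.0  # all values tied across both groups
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(dict(group_a=a, group_b=b, statistic=stat, p_raw=p))
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] <= fdr
    return out
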