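"""SparCC correlation inference for compositional count data.

Sequencing counts are compositional: only relative abundances are
observed, so Pearson correlations on proportions are spurious.  SparCC
instead works from the variation matrix ``t_ij = Var[ln(f_i/f_j)]``.
Writing ``omega_i`` for the variance of the (unobserved) log basis
abundance of OTU i,

    t_ij ≈ omega_i + omega_j − 2 rho_ij sqrt(omega_i omega_j),

and under the sparsity assumption (most pairs uncorrelated) the row sums
of ``t`` give a linear system ``M omega = t_rowsums`` with ``M`` having
diagonal D−1 and off-diagonal 1.  Correlations follow as

    rho_ij = (omega_i + omega_j − t_ij) / (2 sqrt(omega_i omega_j)).

Strongly correlated pairs violate sparsity, so the strongest pair is
iteratively excluded from the system and the basis re-solved.  Count
uncertainty is handled by averaging (elementwise median) over Dirichlet
posterior resamples of the fractions, and significance by a permutation
bootstrap that breaks all pairwise association while preserving each
OTU's marginal distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import CorrelationResult, OtuTable, edge_catalog

OMEGA_FLOOR = 1e-10


def _as_counts(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, OtuTable):
        return table.counts, table.otu_ids
    arr = np.asarray(table)
    return arr, [f"OTU_{i + 1}" for i in range(arr.shape[0])]


def estimate_fractions(counts: np.ndarray, seed=None) -> np.ndarray:
    """One Dirichlet posterior resample of per-sample fractions.

    Per sample (column), fractions are drawn from Dirichlet(counts + 1);
    the +1 pseudocount keeps zero counts strictly positive.
    """
    counts = np.asarray(counts)
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError("every sample must have a positive total count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gammas = rng.standard_gamma(counts + 1.0)
    return gammas / gammas.sum(axis=0, keepdims=True)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Variation matrix ``t_ij = Var[ln f_i − ln f_j]`` (sample variance, n−1).

    Computed via the covariance of the log fractions:
    ``t_ij = v_i + v_j − 2 c_ij``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute variances")
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive")
    logf = np.log(fractions)
    c = np.cov(logf, ddof=1)
    v = np.diag(c)
    t = v[:, None] + v[None, :] - 2.0 * c
    t = np.maximum(t, 0.0)
    np.fill_diagonal(t, 0.0)
    return t


def solve_basis_and_rho(
    t: np.ndarray,
    excluded_pairs: np.ndarray | None = None,
    otu_ids=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the basis-variance system and form the correlation matrix.

    ``excluded_pairs`` is a boolean DxD matrix marking pairs removed from
    the sparsity approximation; their contributions are dropped from both
    ``M`` and the row sums.  Basis variances below 1e-10 are floored.
    Returns ``(omega, rho)`` with ``rho`` clipped to [−1, 1].
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < 4:
        raise ValueError("need >= 4 OTUs: the basis-variance system is underdetermined below 4")
    include = np.ones((d, d), dtype=float)
    np.fill_diagonal(include, 0.0)
    if excluded_pairs is not None:
        include[excluded_pairs] = 0.0
        np.fill_diagonal(include, 0.0)
    m = include + np.diag(include.sum(axis=1))
    rowsums = (include * t).sum(axis=1)
    try:
        omega = np.linalg.solve(m, rowsums)
    except np.linalg.LinAlgError:
        ids = otu_ids or [f"OTU_{i + 1}" for i in range(d)]
        few = [ids[i] for i in np.argsort(include.sum(axis=1))[:3]]
        raise ValueError(
            f"basis system singular after exclusions; over-excluded OTUs include {few}"
        ) from None
    omega = np.maximum(omega, OMEGA_FLOOR)
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return omega, rho


def _sparcc_from_variation(
    t: np.ndarray,
    n_exclusion_iters: int,
    exclusion_threshold: float,
) -> np.ndarray:
    """Exclusion loop on one variation matrix; returns a full DxD rho.

    OTUs accumulating >= D_active − 3 exclusions are dropped from the
    system and their correlations set to 0.
    """
    d = t.shape[0]
    excluded = np.zeros((d, d), dtype=bool)
    excl_count = np.zeros(d, dtype=int)
    active = np.ones(d, dtype=bool)

    def _solve():
        idx = np.flatnonzero(active)
        sub_t = t[np.ix_(idx, idx)]
        sub_ex = excluded[np.ix_(idx, idx)]
        _, sub_rho = solve_basis_and_rho(sub_t, sub_ex)
        return idx, sub_rho

    idx, sub_rho = _solve()
    for _ in range(n_exclusion_iters):
        cand = np.abs(sub_rho).copy()
        cand[excluded[np.ix_(idx, idx)]] = -np.inf
        np.fill_diagonal(cand, -np.inf)
        flat = int(np.argmax(cand))
        i_loc, j_loc = np.unravel_index(flat, cand.shape)
        if cand[i_loc, j_loc] <= exclusion_threshold:
            break
        gi, gj = idx[i_loc], idx[j_loc]
        excluded[gi, gj] = excluded[gj, gi] = True
        excl_count[gi] += 1
        excl_count[gj] += 1
        d_active = int(active.sum())
        drop = active & (excl_count >= d_active - 3)
        if drop.any():
            active &= ~drop
            if active.sum() < 4:
                warnings.warn("exclusion dropped too many OTUs; stopping exclusion early")
                active |= drop  # revert; keep last solvable system
                break
        idx, sub_rho = _solve()

    rho = np.zeros((d, d))
    rho[np.ix_(idx, idx)] = sub_rho
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc(
    table,
    n_dirichlet: int = 50,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """SparCC point estimate: elementwise median over Dirichlet resamples."""
    counts, _ = _as_counts(table)
    d, n = counts.shape
    if d < 4:
        raise ValueError("need >= 4 OTUs: the basis-variance system is underdetermined below 4")
    if n < 10:
        raise ValueError("need >= 10 samples for a meaningful SparCC estimate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rhos = np.empty((n_dirichlet, d, d))
    for b in range(n_dirichlet):
        fractions = estimate_fractions(counts, rng)
        t = log_ratio_variances(fractions)
        rhos[b] = _sparcc_from_variation(t, n_exclusion_iters, exclusion_threshold)
    rho = np.median(rhos, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_pvalues(
    table,
    rho_observed: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = 0,
    n_dirichlet: int = 5,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
) -> np.ndarray:
    """Two-sided permutation-bootstrap p-values for a SparCC estimate.

    Each bootstrap dataset permutes every OTU's counts across samples
    independently, destroying pairwise association while preserving
    marginals; SparCC is re-run (with a reduced number of Dirichlet
    resamples) and ``p_ij = (1 + #{|rho_boot| >= |rho_obs|}) / (1 + B)``.
    """
    counts, _ = _as_counts(table)
    if n_bootstrap < 20:
        warnings.warn("fewer than 20 bootstraps: p-value resolution is coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    abs_obs = np.abs(np.asarray(rho_observed))
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_bootstrap):
        perm = rng.permuted(counts, axis=1)
        rho_b = sparcc(
            perm,
            n_dirichlet=n_dirichlet,
            n_exclusion_iters=n_exclusion_iters,
            exclusion_threshold=exclusion_threshold,
            seed=rng,
        )
        exceed += np.abs(rho_b) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_bootstrap)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 1.0)
    return p


def significant_pairs(rho, p, otu_ids=None, alpha: float = 0.05, site: str = ""):
    """Edge catalog of unordered pairs with p strictly below ``alpha``."""
    rho = np.asarray(rho)
    p = np.asarray(p)
    if rho.shape != p.shape:
        raise ValueError("rho and p shapes differ")
    d = rho.shape[0]
    if otu_ids is None:
        otu_ids = [f"OTU_{i + 1}" for i in range(d)]
    iu, ju = np.triu_indices(d, k=1)
    keep = p[iu, ju] < alpha
    records = [
        (otu_ids[i], otu_ids[j], float(rho[i, j]), float(p[i, j]), site)
        for i, j in zip(iu[keep], ju[keep])
    ]
    return edge_catalog(records)


def clr_correlation(table, pseudocount: float = 1.0) -> np.ndarray:
    """Pearson correlation of clr-transformed counts.

    The centred log-ratio is the naive compositional baseline; used as an
    independent comparison for SparCC estimates, not as the inference.
    """
    counts, _ = _as_counts(table)
    f = (counts + pseudocount) / (counts + pseudocount).sum(axis=0, keepdims=True)
    logf = np.log(f)
    clr = logf - logf.mean(axis=0, keepdims=True)
    return np.corrcoef(clr)


class SparCC(BaseEstimator):
    """Sklearn-style estimator wrapping SparCC inference.

    ``fit`` expects ``X`` of shape (n_samples, n_otus) of non-negative
    integer counts (sklearn orientation; note :class:`OtuTable` stores the
    transpose) and sets:

    ``correlation_`` : (n_otus, n_otus) SparCC correlation matrix.
    ``pvalues_`` : bootstrap p-values, when ``n_bootstrap > 0``.
    ``settings_`` : the resolved inference settings.

    Parameters mirror the FastSpar defaults: 50 Dirichlet resamples,
    10 exclusion iterations, exclusion threshold 0.1, median aggregation.
    """

    def __init__(
        self,
        n_dirichlet: int = 50,
        n_exclusion_iters: int = 10,
        exclusion_threshold: float = 0.1,
        n_bootstrap: int = 0,
        bootstrap_dirichlet: int = 5,
        random_state: int | None = 0,
    ):
        self.n_dirichlet = n_dirichlet
        self.n_exclusion_iters = n_exclusion_iters
        self.exclusion_threshold = exclusion_threshold
        self.n_bootstrap = n_bootstrap
        self.bootstrap_dirichlet = bootstrap_dirichlet
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_otus)")
        counts = X.T
        self.correlation_ = sparcc(
            counts,
            n_dirichlet=self.n_dirichlet,
            n_exclusion_iters=self.n_exclusion_iters,
            exclusion_threshold=self.exclusion_threshold,
            seed=self.random_state,
        )
        if self.n_bootstrap > 0:
            self.pvalues_ = sparcc_pvalues(
                counts,
                self.correlation_,
                n_bootstrap=self.n_bootstrap,
                seed=None if self.random_state is None else self.random_state + 1,
                n_dirichlet=self.bootstrap_dirichlet,
                n_exclusion_iters=self.n_exclusion_iters,
                exclusion_threshold=self.exclusion_threshold,
            )
        else:
            self.pvalues_ = None
        self.n_features_in_ = counts.shape[0]
        self.settings_ = dict(
            n_dirichlet=self.n_dirichlet,
            n_exclusion_iters=self.n_exclusion_iters,
            exclusion_threshold=self.exclusion_threshold,
            n_bootstrap=self.n_bootstrap,
            bootstrap_dirichlet=self.bootstrap_dirichlet,
            random_state=self.random_state,
        )
        return self


def correlation_result(
    table: OtuTable,
    n_dirichlet: int = 50,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    n_bootstrap: int = 100,
    bootstrap_dirichlet: int = 5,
    seed: int = 0,
) -> CorrelationResult:
    """Run the full inference (point estimate + p-values) on an OtuTable."""
    est = SparCC(
        n_dirichlet=n_dirichlet,
        n_exclusion_iters=n_exclusion_iters,
        exclusion_threshold=exclusion_threshold,
        n_bootstrap=n_bootstrap,
        bootstrap_dirichlet=bootstrap_dirichlet,
        random_state=seed,
    ).fit(table.counts.T)
    return CorrelationResult(
        otu_ids=table.otu_ids,
        rho=est.correlation_,
        p=est.pvalues_,
        settings=est.settings_,
    )
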