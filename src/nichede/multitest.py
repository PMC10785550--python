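"""Evidence pooling and hierarchical false-discovery-rate control.

Within a gene, one-sided p-values across hypotheses are combined with
Brown's method (a dependence-adjusted Fisher combination using the
Kost-McDermott polynomial approximation to the covariance of -2 log p for
correlated normal statistics).  Across kernel bandwidths, p-values are
pooled with the Cauchy combination test weighted by the per-gene regression
log-likelihoods.  Discoveries are then reported through a gene ->
cell-type -> interaction cascade of Benjamini-Hochberg corrections, with an
overall FDR bound of alpha * (D + F) / (D + 1) where D counts discoveries
and F the BH families run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regression import NicheDEFit, TestStatistics

__all__ = [
    "PValueHierarchy",
    "DiscoverySet",
    "browns_combine",
    "cauchy_combine",
    "likelihood_weights",
    "bh_reject",
    "hierarchical_procedure",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


# ---------------------------------------------------------------------------
# combination primitives
# ---------------------------------------------------------------------------


def _km_cov(rho: np.ndarray) -> np.ndarray:
    """Kost-McDermott cubic: cov(-2 log p_i, -2 log p_j) for one-sided
    p-values of bivariate-normal statistics with correlation rho."""
    return 3.263 * rho + 0.710 * rho**2 + 0.027 * rho**3


def browns_combine(pvals: np.ndarray, corr: np.ndarray | None = None) -> float:
    """Combine dependent one-sided p-values via Brown's method.

    ``corr`` is the correlation matrix of the underlying normal statistics;
    identity (or None) reduces the procedure exactly to Fisher's method.
    The combined statistic X = -2 sum log p is referred to a scaled
    chi-square with moments matched to E[X] = 2k and
    Var[X] = 4k + 2 sum_{j<l} cov_jl.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value set")
    p = np.clip(p, _P_FLOOR, _P_CEIL)
    k = p.size
    if k == 1:
        return float(p[0])
    x = float(-2.0 * np.sum(np.log(p)))
    mean = 2.0 * k
    var = 4.0 * k
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        iu = np.triu_indices(k, k=1)
        var += 2.0 * float(np.sum(_km_cov(corr[iu])))
    if var <= 0:  # defensive: wildly negative correlations
        var = 4.0 * k
    f = 2.0 * mean**2 / var
    c = var / (2.0 * mean)
    return float(stats.chi2.sf(x / c, f))


def cauchy_combine(pvals: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted Cauchy combination: S = sum w_j tan((0.5 - p_j) pi),
    combined p = 0.5 - arctan(S) / pi.  Identical p's are returned exactly."""
    p = np.clip(np.asarray(pvals, dtype=float), _P_FLOOR, _P_CEIL)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value set")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        total = w.sum()
        if total <= 0:
            w = np.full(p.size, 1.0 / p.size)
        else:
            w = w / total
    s = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    return float(min(max(0.5 - np.arctan(s) / np.pi, _P_FLOOR), 1.0))


def likelihood_weights(logliks: np.ndarray) -> np.ndarray:
    """Bandwidth weights w_j = L_j / sum_k L_k from the log-likelihoods.

    For counts models the per-gene log-likelihoods are large and negative
    with similar magnitudes across bandwidths, so the ratio is positive and
    close to uniform.  That near-uniformity is essential: strongly adaptive
    weights (e.g. softmax or max-shifted ratios) select the best-fitting
    bandwidth's p-value and break the Cauchy combination's null calibration.
    Mixed-sign or zero-sum log-likelihoods fall back to exactly uniform
    weights.
    """
    L = np.asarray(logliks, dtype=float)
    if L.size == 0:
        raise ValueError("no log-likelihoods supplied")
    if L.size == 1:
        return np.ones(1)
    total = L.sum()
    same_sign = np.all(L > 0) or np.all(L < 0)
    if not same_sign or not np.isfinite(total) or total == 0:
        return np.full(L.size, 1.0 / L.size)
    w = L / total
    return w / w.sum()


def bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Indices rejected by the Benjamini-Hochberg step-up rule."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return np.nonzero(reject)[0]


# ---------------------------------------------------------------------------
# hierarchy containers
# ---------------------------------------------------------------------------


@dataclass
class PValueHierarchy:
    """Per-bandwidth and Cauchy-pooled p-values at the three levels.

    Arrays are indexed per direction ("pos" for beta > 0, "neg" for
    beta < 0).  NaN marks untested entries.
    """

    gene_names: list[str]
    type_names: list[str]
    bandwidths: list[float]
    per_bandwidth_gene: dict[str, np.ndarray]  # (K, G)
    per_bandwidth_celltype: dict[str, np.ndarray]  # (K, G, T)
    per_bandwidth_interaction: dict[str, np.ndarray]  # (K, G, T, T)
    pooled_gene: dict[str, np.ndarray]  # (G,)
    pooled_celltype: dict[str, np.ndarray]  # (G, T)
    pooled_interaction: dict[str, np.ndarray]  # (G, T, T)
    weights: np.ndarray  # (G, K) likelihood weights; nan where gene unfit


@dataclass
class DiscoverySet:
    """Rejections at the gene, (gene, index) and (gene, index, niche) levels.

    Triples carry the direction sign (+1 up-, -1 downregulated).  The
    hierarchy guarantees that every triple's pair and every pair's gene were
    themselves rejected.
    """

    alpha: float
    genes: set[int] = field(default_factory=set)
    pairs: set[tuple[int, int]] = field(default_factory=set)
    triples: set[tuple[int, int, int, int]] = field(default_factory=set)  # (g, i, n, sign)
    fdr_bound: float = np.nan
    n_families: int = 0

    def triples_unsigned(self) -> set[tuple[int, int, int]]:
        return {(g, i, n) for (g, i, n, _) in self.triples}


# ---------------------------------------------------------------------------
# hierarchical procedure
# ---------------------------------------------------------------------------


def _gene_level_p(
    stats_k: TestStatistics, fit_k: NicheDEFit, g: int, direction: str
) -> float:
    pairs = fit_k.pair_index[g]
    if not pairs:
        return np.nan
    pmat = stats_k.p_pos if direction == "pos" else stats_k.p_neg
    p = np.array([pmat[g, i, n] for (i, n) in pairs])
    ok = np.isfinite(p)
    if not ok.any():
        return np.nan
    corr = fit_k.pair_correlation(g)
    if corr is not None:
        corr = corr[np.ix_(np.nonzero(ok)[0], np.nonzero(ok)[0])]
    return browns_combine(p[ok], corr)


def _celltype_level_p(
    stats_k: TestStatistics, fit_k: NicheDEFit, g: int, i: int, direction: str
) -> float:
    pairs = fit_k.pair_index[g]
    idx = [j for j, (ii, _) in enumerate(pairs) if ii == i]
    if not idx:
        return np.nan
    pmat = stats_k.p_pos if direction == "pos" else stats_k.p_neg
    p = np.array([pmat[g, pairs[j][0], pairs[j][1]] for j in idx])
    ok = np.isfinite(p)
    if not ok.any():
        return np.nan
    corr = fit_k.pair_correlation(g)
    if corr is not None:
        sub = np.asarray(idx)[np.nonzero(ok)[0]]
        corr = corr[np.ix_(sub, sub)]
    return browns_combine(p[ok], corr)


def hierarchical_procedure(
    stats_per_bandwidth: list[TestStatistics],
    fits_per_bandwidth: list[NicheDEFit],
    alpha: float = 0.05,
) -> tuple[DiscoverySet, PValueHierarchy]:
    """Run the full multi-bandwidth hierarchical testing cascade.

    Per bandwidth and direction, interaction p-values come from the
    one-sided Wald tests; cell-type p-values combine niche types within
    (gene, index) via Brown's method; gene p-values combine all fitted
    pairs.  Each level is then Cauchy-pooled across bandwidths with
    likelihood weights, and the two one-sided families are processed as two
    parallel BH hierarchies at level ``alpha`` each.
    """
    K = len(stats_per_bandwidth)
    fit0 = fits_per_bandwidth[0]
    G, T = fit0.n_genes, fit0.n_types
    directions = ("pos", "neg")

    pbw_gene = {d: np.full((K, G), np.nan) for d in directions}
    pbw_ct = {d: np.full((K, G, T), np.nan) for d in directions}
    pbw_int = {d: np.full((K, G, T, T), np.nan) for d in directions}
    for k, (st, ft) in enumerate(zip(stats_per_bandwidth, fits_per_bandwidth)):
        for d in directions:
            pbw_int[d][k] = st.p_pos if d == "pos" else st.p_neg
        for g in range(G):
            if not ft.pair_index[g]:
                continue
            for d in directions:
                pbw_gene[d][k, g] = _gene_level_p(st, ft, g, d)
                for i in {i for (i, _) in ft.pair_index[g]}:
                    pbw_ct[d][k, g, i] = _celltype_level_p(st, ft, g, i, d)

    logliks = np.column_stack([ft.loglik for ft in fits_per_bandwidth])  # (G, K)
    weights = np.full((G, K), np.nan)
    pooled_gene = {d: np.full(G, np.nan) for d in directions}
    pooled_ct = {d: np.full((G, T), np.nan) for d in directions}
    pooled_int = {d: np.full((G, T, T), np.nan) for d in directions}
    for g in range(G):
        avail = np.isfinite(logliks[g])
        if not avail.any():
            continue
        w_avail = likelihood_weights(logliks[g, avail])
        weights[g, avail] = w_avail
        for d in directions:
            pg = pbw_gene[d][:, g]
            ok = avail & np.isfinite(pg)
            if ok.any():
                pooled_gene[d][g] = cauchy_combine(pg[ok], weights[g, ok])
            for i in range(T):
                pc = pbw_ct[d][:, g, i]
                ok = avail & np.isfinite(pc)
                if ok.any():
                    pooled_ct[d][g, i] = cauchy_combine(pc[ok], weights[g, ok])
                for n in range(T):
                    pi_ = pbw_int[d][:, g, i, n]
                    ok = avail & np.isfinite(pi_)
                    if ok.any():
                        pooled_int[d][g, i, n] = cauchy_combine(pi_[ok], weights[g, ok])

    discoveries = DiscoverySet(alpha=alpha)
    n_families = 0
    n_disc = 0
    for d in directions:
        sign = +1 if d == "pos" else -1
        gene_idx = np.nonzero(np.isfinite(pooled_gene[d]))[0]
        if gene_idx.size == 0:
            continue
        n_families += 1  # the root gene-level family
        rej_genes = gene_idx[bh_reject(pooled_gene[d][gene_idx], alpha)]
        n_disc += rej_genes.size
        discoveries.genes.update(int(g) for g in rej_genes)
        for g in rej_genes:
            ct_idx = np.nonzero(np.isfinite(pooled_ct[d][g]))[0]
            if ct_idx.size == 0:
                continue
            n_families += 1
            rej_ct = ct_idx[bh_reject(pooled_ct[d][g, ct_idx], alpha)]
            n_disc += rej_ct.size
            discoveries.pairs.update((int(g), int(i)) for i in rej_ct)
            for i in rej_ct:
                ni_idx = np.nonzero(np.isfinite(pooled_int[d][g, i]))[0]
                if ni_idx.size == 0:
                    continue
                n_families += 1
                rej_ni = ni_idx[bh_reject(pooled_int[d][g, i, ni_idx], alpha)]
                n_disc += rej_ni.size
                discoveries.triples.update(
                    (int(g), int(i), int(n), sign) for n in rej_ni
                )
    discoveries.n_families = n_families
    discoveries.fdr_bound = alpha * (n_disc + n_families) / (n_disc + 1.0)

    hierarchy = PValueHierarchy(
        gene_names=fit0.gene_names,
        type_names=fit0.type_names,
        bandwidths=[ft.bandwidth for ft in fits_per_bandwidth],
        per_bandwidth_gene=pbw_gene,
        per_bandwidth_celltype=pbw_ct,
        per_bandwidth_interaction=pbw_int,
        pooled_gene=pooled_gene,
        pooled_celltype=pooled_ct,
        pooled_interaction=pooled_int,
        weights=weights,
    )
    return discoveries, hierarchy
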