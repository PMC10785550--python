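"""Per-gene niche-DE regression.

For each gene g the model is a counts regression with offset,

    log E[y_s] = log mu_{s,g} + sum_{(i,n)} p_{s,i,g} * N_{sigma,s,n} * beta_{i,n}
                 + batch intercepts,

fit by Poisson iteratively reweighted least squares.  Holding the
coefficients fixed, a per-gene negative-binomial dispersion is then
estimated by bounded 1-D likelihood optimization.  Standard errors use the
sandwich covariance of the Poisson estimator with the estimated NB variance
function (or, under the optional full NB refit, the NB Fisher information
at the NB optimum).  The NB parameterization is mean mu, variance
mu + mu^2 / size, with size = 1 / overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "NicheDEFit",
    "TestStatistics",
    "FitConfig",
    "select_testable",
    "build_design",
    "fit_gene",
    "fit_all_genes",
    "wald_one_sided",
    "contrast_markers",
]

_SEPARATION_BOUND = 20.0
_DISPERSION_BOUNDS = (1e-4, 1e4)


@dataclass
class FitConfig:
    max_iter: int = 25
    tol: float = 1e-8
    refit_nb: bool = False
    min_extra_obs: int = 5  # need >= n_columns + this many usable observations


@dataclass
class GeneFit:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    dispersion: float
    converged: bool
    n_obs: int


@dataclass
class NicheDEFit:
    """Coefficients and uncertainties for every gene at one bandwidth."""

    gene_names: list[str]
    type_names: list[str]
    bandwidth: float
    beta: np.ndarray  # (G, T, T) index x niche; 0 where untested
    se: np.ndarray  # (G, T, T); nan where untested
    tested: np.ndarray  # (G, T, T) bool
    loglik: np.ndarray  # (G,)
    dispersion: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    pair_index: list[list[tuple[int, int]]]  # per gene, fitted (i, n) pairs
    pair_cov: list[np.ndarray | None]  # per gene, covariance of pair coefs
    batch_coefs: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def pair_correlation(self, g: int) -> np.ndarray | None:
        """Correlation matrix of the gene's pair Wald statistics."""
        cov = self.pair_cov[g]
        if cov is None or cov.size == 0:
            return None
        sd = np.sqrt(np.diag(cov))
        sd = np.where(sd <= 0, 1.0, sd)
        return cov / np.outer(sd, sd)


@dataclass
class TestStatistics:
    """One-sided Wald statistics and p-values, aligned with a NicheDEFit."""

    t_stat: np.ndarray  # (G, T, T); nan where untested
    p_pos: np.ndarray  # upper tail: evidence for beta > 0
    p_neg: np.ndarray  # lower tail: evidence for beta < 0
    tested: np.ndarray


# ---------------------------------------------------------------------------
# filters and design
# ---------------------------------------------------------------------------


def select_testable(
    counts: np.ndarray,
    cell_counts: np.ndarray,
    niche_raw: np.ndarray,
    reference_expression: np.ndarray,
    min_total_count: float = 100,
    min_pair_obs: int = 30,
    expr_percentile: float = 80.0,
) -> np.ndarray:
    """Boolean (gene, index, niche) mask of testable hypotheses.

    A triple (g, i, n) is testable iff
      1. gene g's total (post-capping) count exceeds ``min_total_count``
         (strict);
      2. strictly more than ``min_pair_obs`` observations both contain index
         type i (``n_{s,i} > 0``) and have niche type n in their
         pre-standardized effective niche (``N_{sigma,s,n} > 0``);
      3. gene g lies in the top ``expr_percentile`` percent of reference
         expression for type i, i.e. at or above the (100 - percentile)-th
         empirical percentile of ``A_{i,.}`` (inclusive).
    """
    counts = np.asarray(counts)
    cell_counts = np.asarray(cell_counts, dtype=float)
    niche_raw = np.asarray(niche_raw, dtype=float)
    A = np.asarray(reference_expression, dtype=float)
    G = counts.shape[1]
    T = cell_counts.shape[1]

    cond1 = counts.sum(axis=0) > min_total_count  # (G,)
    has_index = cell_counts > 0  # (S, T)
    has_niche = niche_raw > 0  # (S, T)
    pair_obs = has_index.astype(np.int64).T @ has_niche.astype(np.int64)  # (T, T)
    cond2 = pair_obs > min_pair_obs
    cutoffs = np.percentile(A, 100.0 - expr_percentile, axis=1)  # (T,)
    cond3 = A >= cutoffs[:, None]  # (T, G)

    mask = (
        cond1[:, None, None]
        & cond2[None, :, :]
        & cond3.T[:, :, None]  # (G, T, 1) broadcast over niche axis
    )
    return mask


def build_design(
    p_gene: np.ndarray,
    niche_std: np.ndarray,
    pairs: list[tuple[int, int]],
    batch_onehot: np.ndarray | None = None,
) -> np.ndarray:
    """Design matrix for one gene: one column p_{s,i} * N_{s,n} per pair,
    plus per-batch intercept columns (a single intercept when unbatched)."""
    S = niche_std.shape[0]
    cols = [p_gene[:, i] * niche_std[:, n] for (i, n) in pairs]
    if batch_onehot is None:
        batch_onehot = np.ones((S, 1))
    X = np.column_stack(cols + [batch_onehot]) if cols else np.asarray(batch_onehot, dtype=float)
    return X


# ---------------------------------------------------------------------------
# likelihoods and the per-gene fit
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, size: float) -> float:
    """Negative-binomial log-likelihood, mean mu, variance mu + mu^2/size."""
    mu = np.clip(mu, 1e-12, None)
    return float(
        np.sum(
            gammaln(y + size)
            - gammaln(size)
            - gammaln(y + 1.0)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


def _estimate_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Maximize the NB likelihood over the size parameter, beta held fixed.

    Searches log-size on the bounded interval; the method-of-moments value
    only matters as a sanity fallback when the optimizer fails.
    """
    lo, hi = np.log(_DISPERSION_BOUNDS[0]), np.log(_DISPERSION_BOUNDS[1])
    res = optimize.minimize_scalar(
        lambda ls: -_nb_loglik(y, mu, np.exp(ls)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:  # pragma: no cover - bounded search essentially always succeeds
        resid = np.mean((y - mu) ** 2 - mu)
        mom = np.mean(mu**2) / resid if resid > 0 else _DISPERSION_BOUNDS[1]
        return float(np.clip(mom, *_DISPERSION_BOUNDS))
    return float(np.exp(res.x))


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    weights_fn,
    max_iter: int,
    tol: float,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Log-link IRLS; ``weights_fn(mu)`` supplies the working weights."""
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        W = weights_fn(mu)
        z = (eta - offset) + (y - mu) / np.clip(mu, 1e-12, None)
        XtW = X.T * W
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        ll = float(np.sum(y * np.clip(eta, -30.0, 30.0) - mu))  # Poisson kernel
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    return beta, mu, converged


def fit_gene(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    config: FitConfig | None = None,
    beta0: np.ndarray | None = None,
) -> GeneFit:
    """Fit one gene: Poisson IRLS, then dispersion, then sandwich SEs.

    With ``config.refit_nb`` the coefficients are refit once with NB working
    weights at the estimated dispersion (off by default).  ``beta0`` warm-
    starts the IRLS iteration.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float)
    beta, mu, converged = _irls(
        y, X, offset, lambda m: m, config.max_iter, config.tol, beta0=beta0
    )
    if np.any(np.abs(beta) > _SEPARATION_BOUND):
        converged = False
    size = _estimate_dispersion(y, mu)
    if config.refit_nb and converged:
        beta, mu, converged = _irls(
            y,
            X,
            offset,
            lambda m: m / (1.0 + m / size),
            config.max_iter,
            config.tol,
            beta0=beta,
        )
        size = _estimate_dispersion(y, mu)
        # at the NB maximum the Fisher information is the right curvature
        w_nb = mu / (1.0 + mu / size)
        info = (X.T * w_nb) @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
    else:
        # the coefficients are the Poisson MLE, not the NB one, so their
        # asymptotic covariance is the sandwich A^-1 B A^-1 with A the
        # Poisson information and B built from the NB variance mu + mu^2/size
        # (the plain NB information is anti-conservative here)
        info_pois = (X.T * mu) @ X
        try:
            a_inv = np.linalg.inv(info_pois)
        except np.linalg.LinAlgError:
            a_inv = np.linalg.pinv(info_pois)
        bread = (X.T * (mu * (1.0 + mu / size))) @ X
        cov = a_inv @ bread @ a_inv
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return GeneFit(
        beta=beta,
        se=se,
        cov=cov,
        loglik=_nb_loglik(y, mu, size),
        dispersion=size,
        converged=converged,
        n_obs=len(y),
    )


def _independent_columns(X: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int(np.sum(diag > rtol * diag[0]))
    return np.sort(piv[:rank])


def fit_all_genes(
    counts: np.ndarray,
    mu: np.ndarray,
    p: np.ndarray,
    niche_std: np.ndarray,
    tested_mask: np.ndarray,
    gene_names: list[str],
    type_names: list[str],
    bandwidth: float,
    batch_labels: np.ndarray | None = None,
    excluded_niche_types: list[int] | None = None,
    config: FitConfig | None = None,
) -> NicheDEFit:
    """Fit the niche-DE regression for every gene at one bandwidth.

    Per gene: observations with ``mu = 0`` are dropped (the log offset is
    undefined there), collinear design columns are removed by pivoted-QR
    rank detection (those pairs are reported untested), and genes with fewer
    usable observations than columns + 5 or failing convergence are skipped.
    """
    config = config or FitConfig()
    S, G = counts.shape
    T = len(type_names)
    excluded = set(excluded_niche_types or [])

    if batch_labels is None:
        batch_onehot = np.ones((S, 1))
        batch_names = ["intercept"]
    else:
        batch_names = sorted(set(map(str, batch_labels)))
        batch_onehot = np.column_stack(
            [np.asarray(batch_labels).astype(str) == b for b in batch_names]
        ).astype(float)

    beta = np.zeros((G, T, T))
    se = np.full((G, T, T), np.nan)
    tested = np.zeros((G, T, T), dtype=bool)
    loglik = np.full(G, np.nan)
    dispersion = np.full(G, np.nan)
    converged = np.zeros(G, dtype=bool)
    pair_index: list[list[tuple[int, int]]] = [[] for _ in range(G)]
    pair_cov: list[np.ndarray | None] = [None] * G
    batch_coefs: dict[str, list[float]] = {b: [] for b in batch_names}

    for g in range(G):
        pairs = [
            (i, n)
            for i in range(T)
            for n in range(T)
            if tested_mask[g, i, n] and n not in excluded
        ]
        if not pairs:
            continue
        usable = mu[:, g] > 0
        if usable.sum() < len(pairs) + batch_onehot.shape[1] + config.min_extra_obs:
            continue
        X_full = build_design(p[:, :, g], niche_std, pairs, batch_onehot)[usable]
        y = counts[usable, g].astype(float)
        offset = np.log(mu[usable, g])
        n_pair = len(pairs)
        keep = _independent_columns(X_full)
        # batch columns must survive; if one was dropped the design is degenerate
        pair_keep = [j for j in keep if j < n_pair]
        col_keep = pair_keep + list(range(n_pair, X_full.shape[1]))
        X = X_full[:, col_keep]
        kept_pairs = [pairs[j] for j in pair_keep]
        if len(y) < X.shape[1] + config.min_extra_obs:
            continue
        fit = fit_gene(y, X, offset, config)
        if not fit.converged:
            continue
        k = len(kept_pairs)
        for j, (i, n) in enumerate(kept_pairs):
            beta[g, i, n] = fit.beta[j]
            se[g, i, n] = fit.se[j]
            tested[g, i, n] = fit.se[j] > 0
        loglik[g] = fit.loglik
        dispersion[g] = fit.dispersion
        converged[g] = True
        pair_index[g] = kept_pairs
        pair_cov[g] = fit.cov[:k, :k]
        for b, val in zip(batch_names, fit.beta[k:]):
            batch_coefs[b].append(float(val))

    return NicheDEFit(
        gene_names=list(gene_names),
        type_names=list(type_names),
        bandwidth=float(bandwidth),
        beta=beta,
        se=se,
        tested=tested,
        loglik=loglik,
        dispersion=dispersion,
        converged=converged,
        pair_index=pair_index,
        pair_cov=pair_cov,
        batch_coefs={b: np.asarray(v) for b, v in batch_coefs.items()},
    )


# ---------------------------------------------------------------------------
# tests on the fit
# ---------------------------------------------------------------------------


def wald_one_sided(fit: NicheDEFit) -> TestStatistics:
    """One-sided Wald z-tests for beta > 0 and beta < 0 per (g, i, n)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(fit.tested, fit.beta / fit.se, np.nan)
    p_pos = np.where(fit.tested, stats.norm.sf(t), np.nan)
    p_neg = np.where(fit.tested, stats.norm.cdf(t), np.nan)
    return TestStatistics(t_stat=t, p_pos=p_pos, p_neg=p_neg, tested=fit.tested.copy())


def contrast_markers(
    fit: NicheDEFit,
    gene: int,
    index_type: int,
    niche_pos: int,
    niche_neg: int,
    alpha: float = 0.05,
    stats_table: TestStatistics | None = None,
) -> dict:
    """One-sided contrast test beta_{i,n1} - beta_{i,n2} > 0 for one gene.

    The gene is called an (i, n1) marker when its (i, n1) effect is itself
    significantly positive at ``alpha`` and the contrast rejects.
    """
    pairs = fit.pair_index[gene]
    cov = fit.pair_cov[gene]
    key1, key2 = (index_type, niche_pos), (index_type, niche_neg)
    if cov is None or key1 not in pairs or key2 not in pairs:
        return {"testable": False, "p_value": np.nan, "statistic": np.nan, "marker": False}
    j1, j2 = pairs.index(key1), pairs.index(key2)
    diff = fit.beta[gene, index_type, niche_pos] - fit.beta[gene, index_type, niche_neg]
    var = cov[j1, j1] + cov[j2, j2] - 2.0 * cov[j1, j2]
    if var <= 0:
        return {"testable": False, "p_value": np.nan, "statistic": np.nan, "marker": False}
    z = diff / np.sqrt(var)
    p = float(stats.norm.sf(z))
    st = stats_table or wald_one_sided(fit)
    own_p = st.p_pos[gene, index_type, niche_pos]
    marker = bool(p < alpha and np.isfinite(own_p) and own_p < alpha)
    return {"testable": True, "p_value": p, "statistic": float(z), "marker": marker}
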