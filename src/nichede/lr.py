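"""Ligand-receptor inference from niche-DE statistics (niche-LR).

For a sender (niche) type n and receiver (index) type i, each ligand's
activity is the prior-weighted sum of the one-sided niche-DE statistics of
its top target genes, standardized by its null standard error
sqrt(sum W_j^2).  Ligands passing the activity threshold max(1.64, T_(M))
become candidates and are then confirmed by checking that the ligand is
actually expressed by the niche type and its receptor by the index type,
via Poisson regressions of observed expression on the spot composition
(or, at single-cell resolution, expression-rank filters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LigandPrior
from .multitest import bh_reject
from .regression import FitConfig, NicheDEFit, TestStatistics, fit_gene

logger = logging.getLogger(__name__)

__all__ = [
    "LigandActivityTable",
    "select_ligand_bandwidth",
    "top_targets_and_weights",
    "ligand_activity",
    "candidate_ligands",
    "confirm_ligand",
    "confirm_receptor",
    "singlecell_expression_filter",
    "run_niche_lr",
]

_ACTIVITY_FLOOR = 1.64
_MIN_MASK_OBS = 10


@dataclass
class LigandActivityTable:
    """Tidy per-(ligand, index, niche) activity and confirmation results."""

    table: pd.DataFrame

    def confirmed_pairs(self) -> list[tuple[str, str]]:
        sub = self.table[self.table["confirmed"]]
        return list(zip(sub["ligand"], sub["receptor"]))


def select_ligand_bandwidth(logliks: np.ndarray, bandwidths: list[float]) -> int:
    """Index of the bandwidth maximizing the ligand's regression
    log-likelihood; ties and NaN-free ties break toward the smaller
    bandwidth (grids are sorted ascending)."""
    L = np.asarray(logliks, dtype=float)
    if L.size != len(bandwidths):
        raise ValueError("one log-likelihood per bandwidth required")
    if not np.isfinite(L).any():
        raise ValueError("ligand was not fit at any bandwidth")
    order = np.argsort(np.asarray(bandwidths))
    best = order[int(np.nanargmax(L[order]))]
    return int(best)


def top_targets_and_weights(
    prior: LigandPrior,
    ligand: str,
    data_genes: list[str],
    n_targets: int = 50,
) -> tuple[list[str], np.ndarray]:
    """Top-K prior targets of a ligand among genes present in the data,
    with weights W_j = A_{l,g_j} / sum_k A_{l,g_k}."""
    li = prior.ligand_names.index(ligand)
    gene_pos = {g: j for j, g in enumerate(prior.gene_names)}
    present = [g for g in data_genes if g in gene_pos]
    vals = np.array([prior.ligand_target[li, gene_pos[g]] for g in present])
    nonzero = vals > 0
    present = [g for g, nz in zip(present, nonzero) if nz]
    vals = vals[nonzero]
    if len(present) == 0:
        raise ValueError(f"ligand {ligand!r} has no overlapping prior targets")
    if len(present) < n_targets:
        logger.warning(
            "ligand %s: only %d overlapping targets (requested %d)",
            ligand,
            len(present),
            n_targets,
        )
        k = len(present)
    else:
        k = n_targets
    order = np.argsort(-vals, kind="stable")[:k]
    targets = [present[j] for j in order]
    weights = vals[order] / vals[order].sum()
    return targets, weights


def ligand_activity(weights: np.ndarray, target_stats: np.ndarray) -> tuple[float, float]:
    """Raw and standardized activity score from target one-sided statistics.

    Untested targets enter with statistic 0 (conservative); under the null
    the standardized score is approximately standard normal.
    """
    w = np.asarray(weights, dtype=float)
    b = np.nan_to_num(np.asarray(target_stats, dtype=float), nan=0.0)
    t_raw = float(np.sum(w * b))
    return t_raw, t_raw / float(np.sqrt(np.sum(w**2)))


def candidate_ligands(scores: dict[str, float], max_candidates: int = 50) -> set[str]:
    """Ligands with activity strictly above max(1.64, M-th largest score).

    When fewer than M ligands were scored the order-statistic cap is moot
    and only the 1.64 floor applies.
    """
    if not scores:
        return set()
    vals = np.sort(np.array(list(scores.values())))[::-1]
    if vals.size < max_candidates:
        threshold = _ACTIVITY_FLOOR
    else:
        threshold = max(_ACTIVITY_FLOOR, float(vals[max_candidates - 1]))
    return {l for l, t in scores.items() if t > threshold}


def _composition_regression_p(
    y: np.ndarray,
    cell_counts: np.ndarray,
    mask: np.ndarray,
    test_type: int,
) -> float:
    """One-sided p for a positive coefficient of one cell type in a Poisson
    regression of expression on the composition matrix, within a mask."""
    if mask.sum() < _MIN_MASK_OBS:
        return np.nan
    y_m = y[mask].astype(float)
    if y_m.sum() == 0:
        return np.nan
    X = cell_counts[mask]
    keep = X.sum(axis=0) > 0
    if not keep[test_type]:
        return np.nan
    # intercept term plus one column per cell type, warm-started at the
    # mean rate so the exponential model does not overshoot on large counts
    X = np.column_stack([X[:, keep], np.ones(int(mask.sum()))])
    beta0 = np.zeros(X.shape[1])
    beta0[-1] = np.log(y_m.mean())
    fit = fit_gene(
        y_m, X, np.zeros(int(mask.sum())), FitConfig(max_iter=100), beta0=beta0
    )
    if not fit.converged:
        return np.nan
    col = int(np.nonzero(keep)[0].tolist().index(test_type))
    if fit.se[col] <= 0:
        return np.nan
    return float(stats.norm.sf(fit.beta[col] / fit.se[col]))


def confirm_ligand(
    ligand_counts: np.ndarray,
    cell_counts: np.ndarray,
    niche_mask: np.ndarray,
    niche_type: int,
) -> float:
    """p-value that the ligand's expression rises with niche-type abundance,
    among observations with the index type in their effective niche."""
    return _composition_regression_p(ligand_counts, cell_counts, niche_mask, niche_type)


def confirm_receptor(
    receptor_counts: np.ndarray,
    cell_counts: np.ndarray,
    niche_mask: np.ndarray,
    index_type: int,
) -> float:
    """p-value that the receptor's expression rises with index-type
    abundance, among observations with the niche type in their niche."""
    return _composition_regression_p(receptor_counts, cell_counts, niche_mask, index_type)


def singlecell_expression_filter(
    type_mean_expression: np.ndarray,
    gene_index: int,
    top_percent: float,
) -> bool:
    """At single-cell resolution: does the gene rank in the top
    ``top_percent`` % of the type's expressed genes (inclusive boundary)?"""
    expr = np.asarray(type_mean_expression, dtype=float)
    rank = int(np.sum(expr > expr[gene_index])) + 1  # 1 = highest
    return rank <= max(1, int(np.ceil(top_percent / 100.0 * expr.size)))


def run_niche_lr(
    fits: list[NicheDEFit],
    stats_tables: list[TestStatistics],
    niches_raw: list[np.ndarray],
    counts: np.ndarray,
    cell_counts: np.ndarray,
    prior: LigandPrior,
    index_type: int,
    niche_type: int,
    n_targets: int = 50,
    max_candidates: int = 50,
    alpha: float = 0.05,
    resolution: str = "spot",
) -> LigandActivityTable:
    """Full niche-LR pass for one (index, niche) cell-type pair.

    Returns one row per (ligand, receptor) combination among ligands scored,
    flagging candidates, per-regression p-values, and confirmed pairs.
    """
    gene_names = fits[0].gene_names
    gene_pos = {g: j for j, g in enumerate(gene_names)}
    bandwidths = [f.bandwidth for f in fits]
    # fallback bandwidth: highest total log-likelihood over all fitted genes
    total_ll = [np.nansum(f.loglik) if np.isfinite(f.loglik).any() else -np.inf for f in fits]
    fallback_k = int(np.argmax(total_ll))

    rows = []
    scores: dict[str, float] = {}
    sigma_star: dict[str, int] = {}
    for ligand in prior.ligand_names:
        try:
            targets, weights = top_targets_and_weights(
                prior, ligand, gene_names, n_targets
            )
        except ValueError:
            continue
        if ligand in gene_pos:
            ll = np.array([f.loglik[gene_pos[ligand]] for f in fits])
            k_star = (
                select_ligand_bandwidth(ll, bandwidths)
                if np.isfinite(ll).any()
                else fallback_k
            )
        else:
            k_star = fallback_k
        st = stats_tables[k_star]
        b = np.array(
            [st.t_stat[gene_pos[g], index_type, niche_type] for g in targets]
        )
        _, t_std = ligand_activity(weights, b)
        scores[ligand] = t_std
        sigma_star[ligand] = k_star

    candidates = candidate_ligands(scores, max_candidates)

    # confirmation regressions (spot mode) or expression-rank filters (SC)
    ligand_p: dict[str, float] = {}
    for ligand in candidates:
        k_star = sigma_star[ligand]
        if ligand not in gene_pos:
            ligand_p[ligand] = np.nan
            continue
        mask = niches_raw[k_star][:, index_type] > 0
        if resolution == "single_cell":
            sender = cell_counts[:, niche_type] > 0
            sub = mask & sender
            if sub.sum() < _MIN_MASK_OBS:
                ligand_p[ligand] = np.nan
                continue
            mean_expr = counts[sub].mean(axis=0)
            ok = singlecell_expression_filter(mean_expr, gene_pos[ligand], alpha * 100)
            ligand_p[ligand] = 0.0 if ok else 1.0
        else:
            ligand_p[ligand] = confirm_ligand(
                counts[:, gene_pos[ligand]], cell_counts, mask, niche_type
            )

    tested_ligands = [l for l in sorted(candidates) if np.isfinite(ligand_p.get(l, np.nan))]
    conf_ligands: set[str] = set()
    if tested_ligands:
        pvec = np.array([ligand_p[l] for l in tested_ligands])
        rej = bh_reject(pvec, alpha)
        conf_ligands = {tested_ligands[j] for j in rej}

    receptor_jobs: list[tuple[str, str]] = []
    for ligand in sorted(conf_ligands):
        for receptor in prior.receptors_of(ligand):
            if receptor in gene_pos:
                receptor_jobs.append((ligand, receptor))
    receptor_p: dict[tuple[str, str], float] = {}
    for ligand, receptor in receptor_jobs:
        k_star = sigma_star[ligand]
        mask = niches_raw[k_star][:, niche_type] > 0
        if resolution == "single_cell":
            receiver = cell_counts[:, index_type] > 0
            sub = mask & receiver
            if sub.sum() < _MIN_MASK_OBS:
                receptor_p[(ligand, receptor)] = np.nan
                continue
            mean_expr = counts[sub].mean(axis=0)
            ok = singlecell_expression_filter(mean_expr, gene_pos[receptor], alpha * 100)
            receptor_p[(ligand, receptor)] = 0.0 if ok else 1.0
        else:
            receptor_p[(ligand, receptor)] = confirm_receptor(
                counts[:, gene_pos[receptor]], cell_counts, mask, index_type
            )
    confirmed_pairs: set[tuple[str, str]] = set()
    tested_pairs = [
        pr for pr in receptor_jobs if np.isfinite(receptor_p.get(pr, np.nan))
    ]
    if tested_pairs:
        pvec = np.array([receptor_p[pr] for pr in tested_pairs])
        rej = bh_reject(pvec, alpha)
        confirmed_pairs = {tested_pairs[j] for j in rej}

    itype = fits[0].type_names[index_type]
    ntype = fits[0].type_names[niche_type]
    for ligand in sorted(scores):
        receptors = [r for r in prior.receptors_of(ligand)] or [""]
        for receptor in receptors:
            rows.append(
                {
                    "ligand": ligand,
                    "receptor": receptor,
                    "index_type": itype,
                    "niche_type": ntype,
                    "sigma_star": bandwidths[sigma_star[ligand]],
                    "activity_T": scores[ligand],
                    "candidate": ligand in candidates,
                    "ligand_p": ligand_p.get(ligand, np.nan),
                    "receptor_p": receptor_p.get((ligand, receptor), np.nan),
                    "confirmed": (ligand, receptor) in confirmed_pairs,
                }
            )
    return LigandActivityTable(table=pd.DataFrame(rows))
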