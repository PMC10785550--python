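"""Model / Results interface for niche-differential expression analysis.

:class:`NicheDEModel` is built from a spatial dataset, a reference profile
and a per-observation composition; :meth:`NicheDEModel.fit` runs the whole
estimation pipeline (capping, expectation construction, effective niches
per bandwidth, per-gene regressions) and returns a
:class:`NicheDEResults` carrying coefficients, standard errors, one-sided
tests and everything downstream hangs off: the hierarchical FDR cascade,
marker contrasts, and niche-LR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lr as lr_mod
from .io import Composition, LigandPrior, ReferenceProfile, SpatialDataset
from .multitest import DiscoverySet, PValueHierarchy, hierarchical_procedure
from .niche import (
    EffectiveNiche,
    compute_effective_niche,
    default_bandwidths,
    standardize_niche,
)
from .regression import (
    FitConfig,
    NicheDEFit,
    TestStatistics,
    contrast_markers,
    fit_all_genes,
    select_testable,
    wald_one_sided,
)
from .spot import (
    cap_counts,
    estimate_cells_per_spot,
    expected_spot_expression,
    expression_proportions,
    scale_singlecell_means,
    threshold_proportions,
)

__all__ = ["NicheDEModel", "NicheDEResults"]


@dataclass
class FilterConfig:
    min_type_proportion: float = 0.05
    cap_percentile: float = 99.5
    min_total_count: float = 100.0
    min_pair_obs: int = 30
    expr_percentile: float = 80.0
    per_type_min: dict | None = None
    p_threshold: float = 0.05  # expression-source proportion floor


class NicheDEModel:
    """Niche-DE regression model for one spatial sample.

    Parameters
    ----------
    dataset
        Counts plus coordinates.
    reference
        Cell-type mean expression and mean library sizes.
    composition
        Hard labels (single-cell) or deconvolution proportions (spots).
    bandwidths
        Kernel bandwidth grid in coordinate units, or ``"auto"`` for the
        1st/5th/10th percentiles of the pairwise-distance distribution.
    include_self
        Whether an observation contributes to its own effective niche.
    """

    def __init__(
        self,
        dataset: SpatialDataset,
        reference: ReferenceProfile,
        composition: Composition,
        bandwidths: list[float] | str = "auto",
        include_self: bool = True,
        filters: FilterConfig | None = None,
        fit_config: FitConfig | None = None,
        apply_proportion_threshold: bool | None = None,
        batch_labels: np.ndarray | None = None,
        external_niches: list[EffectiveNiche] | None = None,
    ) -> None:
        if dataset.coords is None and external_niches is None:
            raise ValueError("dataset needs coordinates (or supply external niches)")
        if dataset.gene_names and reference.gene_names:
            if dataset.gene_names != reference.gene_names:
                raise ValueError(
                    "gene names differ between counts and reference; "
                    "use io.intersect_genes first"
                )
        self.dataset = dataset
        self.reference = reference
        self.composition = composition
        self.include_self = include_self
        self.filters = filters or FilterConfig()
        self.fit_config = fit_config or FitConfig()
        self.batch_labels = batch_labels
        self.external_niches = external_niches
        if apply_proportion_threshold is None:
            apply_proportion_threshold = composition.mode == "proportions"
        self.apply_proportion_threshold = apply_proportion_threshold
        if external_niches is not None:
            self.bandwidths = [n.bandwidth for n in external_niches]
        elif bandwidths == "auto":
            self.bandwidths = default_bandwidths(dataset.coords)
        else:
            self.bandwidths = sorted(float(b) for b in bandwidths)
        self._prepared: dict | None = None

    # -- pipeline stages -------------------------------------------------

    def _prepare(self) -> dict:
        """Cap counts and derive mu, p, cell counts, and niches."""
        if self._prepared is not None:
            return self._prepared
        ds, ref = self.dataset, self.reference
        counts = cap_counts(ds.counts, self.filters.cap_percentile)
        comp = self.composition
        if self.apply_proportion_threshold and comp.mode == "proportions":
            comp = threshold_proportions(
                comp, self.filters.min_type_proportion, self.filters.per_type_min
            )
        S, G = counts.shape
        T = comp.n_types

        if ds.resolution == "single_cell":
            labels = np.argmax(comp.proportions, axis=1)
            cell_counts = comp.proportions.copy()  # indicators
            lib = ds.counts.sum(axis=1).astype(float)
            mu = scale_singlecell_means(
                ref.mean_expression, labels, lib, ref.mean_library
            )
            # at single-cell resolution every gene's expression comes from
            # the cell's own type: p reduces to the label indicators
            p = np.broadcast_to(comp.proportions[:, :, None], (S, T, G))
            n_hat = np.ones(S)
        else:
            lib = ds.counts.sum(axis=1).astype(float)
            n_hat, cell_counts = estimate_cells_per_spot(
                lib, comp.proportions, ref.mean_library
            )
            mu = expected_spot_expression(cell_counts, ref.mean_expression)
            p = expression_proportions(
                cell_counts, ref.mean_expression, mu, self.filters.p_threshold
            )

        if self.external_niches is not None:
            niches_raw = self.external_niches
        else:
            niches_raw = [
                compute_effective_niche(
                    ds.coords, cell_counts, sigma, comp.type_names, self.include_self
                )
                for sigma in self.bandwidths
            ]
        niches_std = [standardize_niche(nr) for nr in niches_raw]
        self._prepared = {
            "counts": counts,
            "composition": comp,
            "cell_counts": cell_counts,
            "cells_per_spot": n_hat,
            "mu": mu,
            "p": p,
            "niches_raw": niches_raw,
            "niches_std": niches_std,
        }
        return self._prepared

    def fit(self) -> "NicheDEResults":
        """Fit the per-gene regressions at every bandwidth."""
        prep = self._prepare()
        ds, ref = self.dataset, self.reference
        fits: list[NicheDEFit] = []
        for nr, ns in zip(prep["niches_raw"], prep["niches_std"]):
            mask = select_testable(
                prep["counts"],
                prep["cell_counts"],
                nr.matrix,
                ref.mean_expression,
                self.filters.min_total_count,
                self.filters.min_pair_obs,
                self.filters.expr_percentile,
            )
            fits.append(
                fit_all_genes(
                    prep["counts"],
                    prep["mu"],
                    prep["p"],
                    ns.matrix,
                    mask,
                    ds.gene_names or [f"gene_{g}" for g in range(ds.n_genes)],
                    prep["composition"].type_names,
                    nr.bandwidth,
                    batch_labels=self.batch_labels,
                    excluded_niche_types=ns.excluded_types,
                    config=self.fit_config,
                )
            )
        stats_tables = [wald_one_sided(f) for f in fits]
        return NicheDEResults(self, fits, stats_tables, prep)


class NicheDEResults:
    """Fitted niche-DE coefficients and everything downstream.

    Attributes
    ----------
    fits
        One :class:`NicheDEFit` per bandwidth.
    stats
        Matching one-sided Wald statistics per bandwidth.
    """

    def __init__(
        self,
        model: NicheDEModel,
        fits: list[NicheDEFit],
        stats: list[TestStatistics],
        prepared: dict,
    ) -> None:
        self.model = model
        self.fits = fits
        self.stats = stats
        self._prep = prepared
        self._hierarchy_cache: dict[float, tuple[DiscoverySet, PValueHierarchy]] = {}

    @property
    def bandwidths(self) -> list[float]:
        return [f.bandwidth for f in self.fits]

    @property
    def gene_names(self) -> list[str]:
        return self.fits[0].gene_names

    @property
    def type_names(self) -> list[str]:
        return self.fits[0].type_names

    # -- inference -------------------------------------------------------

    def hierarchy(self, alpha: float = 0.05) -> tuple[DiscoverySet, PValueHierarchy]:
        """Hierarchical gene -> cell-type -> interaction FDR cascade."""
        if alpha not in self._hierarchy_cache:
            self._hierarchy_cache[alpha] = hierarchical_procedure(
                self.stats, self.fits, alpha
            )
        return self._hierarchy_cache[alpha]

    def marker_contrast(
        self, gene: str, index_type: str, niche_pos: str, niche_neg: str,
        alpha: float = 0.05, bandwidth_index: int = 0,
    ) -> dict:
        """Contrast test: is the gene's niche upregulation under
        ``niche_pos`` significantly larger than under ``niche_neg``?"""
        g = self.gene_names.index(gene)
        i = self.type_names.index(index_type)
        n1 = self.type_names.index(niche_pos)
        n2 = self.type_names.index(niche_neg)
        return contrast_markers(
            self.fits[bandwidth_index], g, i, n1, n2, alpha,
            self.stats[bandwidth_index],
        )

    def ligand_receptor(
        self,
        prior: LigandPrior,
        index_type: str,
        niche_type: str,
        n_targets: int = 50,
        max_candidates: int = 50,
        alpha: float = 0.05,
    ) -> lr_mod.LigandActivityTable:
        """Niche-LR: infer active ligand-receptor channels for one pair."""
        return lr_mod.run_niche_lr(
            self.fits,
            self.stats,
            [nr.matrix for nr in self._prep["niches_raw"]],
            self._prep["counts"],
            self._prep["cell_counts"],
            prior,
            self.type_names.index(index_type),
            self.type_names.index(niche_type),
            n_targets=n_targets,
            max_candidates=max_candidates,
            alpha=alpha,
            resolution=self.model.dataset.resolution,
        )

    # -- tabular output --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(gene, index, niche, bandwidth) coefficient table."""
        rows = []
        for fit, st in zip(self.fits, self.stats):
            gs, is_, ns = np.nonzero(fit.tested)
            for g, i, n in zip(gs, is_, ns):
                rows.append(
                    {
                        "gene": fit.gene_names[g],
                        "index_type": fit.type_names[i],
                        "niche_type": fit.type_names[n],
                        "bandwidth": fit.bandwidth,
                        "beta": fit.beta[g, i, n],
                        "se": fit.se[g, i, n],
                        "loglik": fit.loglik[g],
                        "dispersion": fit.dispersion[g],
                        "p_pos": st.p_pos[g, i, n],
                        "p_neg": st.p_neg[g, i, n],
                        "tested": True,
                    }
                )
        cols = [
            "gene", "index_type", "niche_type", "bandwidth", "beta", "se",
            "loglik", "dispersion", "p_pos", "p_neg", "tested",
        ]
        return pd.DataFrame(rows, columns=cols)

    def discoveries_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy rejected-hypothesis table across the three levels."""
        disc, hier = self.hierarchy(alpha)
        rows = []
        for g in sorted(disc.genes):
            p = np.nanmin(
                [hier.pooled_gene["pos"][g], hier.pooled_gene["neg"][g]]
            )
            rows.append(
                {
                    "level": "gene",
                    "gene": self.gene_names[g],
                    "index_type": "",
                    "niche_type": "",
                    "direction": "",
                    "p_pooled": p,
                    "rejected": True,
                    "alpha": alpha,
                }
            )
        for g, i in sorted(disc.pairs):
            p = np.nanmin(
                [hier.pooled_celltype["pos"][g, i], hier.pooled_celltype["neg"][g, i]]
            )
            rows.append(
                {
                    "level": "cell_type",
                    "gene": self.gene_names[g],
                    "index_type": self.type_names[i],
                    "niche_type": "",
                    "direction": "",
                    "p_pooled": p,
                    "rejected": True,
                    "alpha": alpha,
                }
            )
        for g, i, n, sign in sorted(disc.triples):
            d = "pos" if sign > 0 else "neg"
            rows.append(
                {
                    "level": "interaction",
                    "gene": self.gene_names[g],
                    "index_type": self.type_names[i],
                    "niche_type": self.type_names[n],
                    "direction": "+" if sign > 0 else "-",
                    "p_pooled": hier.pooled_interaction[d][g, i, n],
                    "rejected": True,
                    "alpha": alpha,
                }
            )
        cols = [
            "level", "gene", "index_type", "niche_type", "direction",
            "p_pooled", "rejected", "alpha",
        ]
        return pd.DataFrame(rows, columns=cols)

    def summary(self, alpha: float = 0.05) -> str:
        """Human-readable overview of the fit and the discovery counts."""
        disc, _ = self.hierarchy(alpha)
        n_fit = int(np.isfinite(self.fits[0].loglik).sum())
        lines = [
            "Niche-DE results",
            "================",
            f"observations:        {self.model.dataset.n_obs}",
            f"genes fit:           {n_fit} / {len(self.gene_names)}",
            f"cell types:          {len(self.type_names)}",
            f"bandwidths:          {', '.join(f'{b:g}' for b in self.bandwidths)}",
            f"alpha:               {alpha}",
            f"niche genes:         {len(disc.genes)}",
            f"(gene, index) pairs: {len(disc.pairs)}",
            f"(g, i, n) triples:   {len(disc.triples)}",
            f"FDR bound:           {disc.fdr_bound:.4g}",
        ]
        return "\n".join(lines)
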