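"""Benchmark designs: null calibration, spike-in power, resolution
degradation, and planted ligand-receptor recovery.

Each benchmark generates its own synthetic inputs through
:mod:`nichede.simulate`, runs the full pipeline through
:class:`~nichede.model.NicheDEModel`, and reports summary rates.  Problem
sizes default to the study conditions (800 spots, 300 genes, 4 types, NB
size 1, spike grid 0.2-1.0, bootstrap sizes 1000/5000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .io import Composition, LigandPrior, ReferenceProfile, SpatialDataset
from .model import FilterConfig, NicheDEModel, NicheDEResults
from .niche import EffectiveNiche, compute_effective_niche, standardize_niche
from .simulate import (
    Fixture,
    SimConfig,
    aggregate_pseudospots,
    apply_bleeding,
    apply_spikein,
    bootstrap_dataset,
    generate_fixture,
    score_recovery,
    simulate_null_counts,
)

__all__ = [
    "pipeline_on_fixture",
    "null_benchmark",
    "power_benchmark",
    "recovery_benchmark",
    "lr_benchmark",
]

_FIXTURE_FILTERS = FilterConfig(min_total_count=100.0, min_pair_obs=30, expr_percentile=80.0)


def _child_seed(ss: np.random.SeedSequence) -> int:
    """Deterministic integer fixture seed from a spawned seed sequence."""
    return int(ss.generate_state(1)[0] % (2**31))


def _truth_mu(fixture: Fixture) -> np.ndarray:
    return fixture.cell_counts @ fixture.reference.mean_expression


def _first_percentile_distance(coords: np.ndarray) -> float:
    d = cdist(coords, coords)
    return float(np.percentile(d[np.triu_indices_from(d, k=1)], 1.0))


def _dataset_from(fixture: Fixture, counts: np.ndarray, sample_id: str) -> SpatialDataset:
    return SpatialDataset(
        obs_ids=[f"{sample_id}_{s}" for s in range(counts.shape[0])],
        counts=counts,
        coords=fixture.coords,
        gene_names=list(fixture.gene_names),
        sample_id=sample_id,
        resolution="single_cell" if fixture.composition.mode == "labels" else "spot",
    )


def pipeline_on_fixture(
    fixture: Fixture,
    counts: np.ndarray,
    bandwidths: list[float] | str = "auto",
    filters: FilterConfig | None = None,
    sample_id: str = "sim",
) -> NicheDEResults:
    """Run the full estimation pipeline on simulated counts."""
    ds = _dataset_from(fixture, counts, sample_id)
    model = NicheDEModel(
        ds,
        fixture.reference,
        fixture.composition,
        bandwidths=bandwidths,
        filters=filters or _FIXTURE_FILTERS,
        apply_proportion_threshold=False,  # simulated compositions are exact
    )
    return model.fit()


# ---------------------------------------------------------------------------
# null / robustness
# ---------------------------------------------------------------------------


@dataclass
class NullBenchmarkResult:
    gene_pvalues: np.ndarray  # pooled gene-level p (pos direction), all reps
    gene_pvalues_bleed: np.ndarray
    ks_pvalue: float
    ks_statistic: float
    ks_statistic_bleed: float
    ks_pvalue_bleed: float
    mean_interaction_fdp: float
    mean_interaction_fdp_bleed: float
    replicate_ks_pvalues: np.ndarray = None  # per-replicate KS uniformity p
    replicate_ks_pvalues_bleed: np.ndarray = None
    replicate_ks_statistics: np.ndarray = None
    replicate_ks_statistics_bleed: np.ndarray = None

    def ks_statistic_change(self) -> float:
        """Relative change of the median per-replicate KS statistic under
        bleeding.  Medians over replicates are used because a single
        aggregate KS statistic is dominated by its own sampling noise when
        the calibration is good, making the ratio unstable."""
        d0 = float(np.median(self.replicate_ks_statistics))
        db = float(np.median(self.replicate_ks_statistics_bleed))
        return abs(db - d0) / d0


def null_benchmark(
    n_replicates: int = 20,
    config: SimConfig | None = None,
    alpha: float = 0.05,
    bleed_alpha: float = 0.25,
    seed: int = 0,
    n_bandwidths: int = 2,
) -> NullBenchmarkResult:
    """Type-I error and spot-swapping robustness under the no-effect model.

    Every gene-level pooled p-value collected across replicates should be
    uniform; every interaction-level rejection is a false discovery.  The
    same replicates are repeated with SpotClean-style bleeding (local
    bleed fraction ``bleed_alpha``, kernel at the 1st distance percentile).
    """
    base = config or SimConfig()
    pvals: list[np.ndarray] = []
    pvals_bleed: list[np.ndarray] = []
    fdp: list[float] = []
    fdp_bleed: list[float] = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep in range(n_replicates):
        fx = generate_fixture(
            SimConfig(**{**base.__dict__, "seed": _child_seed(children[rep])})
        )
        mu = _truth_mu(fx)
        rng = np.random.default_rng(children[rep])
        tau = _first_percentile_distance(fx.coords)
        for contaminated in (False, True):
            if contaminated:
                mu_use = apply_bleeding(mu, bleed_alpha, tau, fx.coords)
                fx_use = _contaminated_fixture(fx, bleed_alpha, tau)
            else:
                mu_use = mu
                fx_use = fx
            counts = simulate_null_counts(mu_use, base.dispersion, rng)
            res = pipeline_on_fixture(
                fx_use,
                counts,
                bandwidths="auto" if n_bandwidths >= 3 else _bw_grid(fx, n_bandwidths),
            )
            disc, hier = res.hierarchy(alpha)
            p = hier.pooled_gene["pos"]
            p = p[np.isfinite(p)]
            n_triples = len(disc.triples)
            rep_fdp = n_triples / max(n_triples, 1)  # all triples are false
            if contaminated:
                pvals_bleed.append(p)
                fdp_bleed.append(rep_fdp)
            else:
                pvals.append(p)
                fdp.append(rep_fdp)
    pv = np.concatenate(pvals)
    pvb = np.concatenate(pvals_bleed)
    ks = stats.kstest(pv, "uniform")
    ksb = stats.kstest(pvb, "uniform")
    return NullBenchmarkResult(
        gene_pvalues=pv,
        gene_pvalues_bleed=pvb,
        ks_pvalue=float(ks.pvalue),
        ks_statistic=float(ks.statistic),
        ks_statistic_bleed=float(ksb.statistic),
        ks_pvalue_bleed=float(ksb.pvalue),
        mean_interaction_fdp=float(np.mean(fdp)),
        mean_interaction_fdp_bleed=float(np.mean(fdp_bleed)),
        replicate_ks_pvalues=np.array(
            [stats.kstest(p, "uniform").pvalue for p in pvals]
        ),
        replicate_ks_pvalues_bleed=np.array(
            [stats.kstest(p, "uniform").pvalue for p in pvals_bleed]
        ),
        replicate_ks_statistics=np.array(
            [stats.kstest(p, "uniform").statistic for p in pvals]
        ),
        replicate_ks_statistics_bleed=np.array(
            [stats.kstest(p, "uniform").statistic for p in pvals_bleed]
        ),
    )


def _contaminated_fixture(fx: Fixture, bleed_alpha: float, tau: float) -> Fixture:
    """Fixture whose composition reflects deconvolution of bled data.

    Marker-based deconvolution of contaminated counts attributes the bled
    transcript mass to extra cells of the source type in the destination
    spot, so the same bleeding operator is applied to the per-type
    transcript mass n_{s,t} * L_t; this is how the spot-swap effect gets
    absorbed into the composition estimates.
    """
    from dataclasses import replace

    mass = fx.cell_counts * fx.reference.mean_library[None, :]
    mass_c = apply_bleeding(mass, bleed_alpha, tau, fx.coords)
    cells_c = mass_c / fx.reference.mean_library[None, :]
    sums = cells_c.sum(axis=1, keepdims=True)
    props = np.divide(cells_c, sums, out=np.zeros_like(cells_c), where=sums > 0)
    comp = Composition(
        type_names=fx.type_names, proportions=props, mode="proportions"
    )
    return replace(fx, composition=comp, cell_counts=cells_c)


def _bw_grid(fixture: Fixture, k: int) -> list[float]:
    d = cdist(fixture.coords, fixture.coords)
    upper = d[np.triu_indices_from(d, k=1)]
    pct = [1.0, 5.0, 10.0][:k]
    return [float(np.percentile(upper, q)) for q in pct]


# ---------------------------------------------------------------------------
# spike-in power
# ---------------------------------------------------------------------------


def power_benchmark(
    betas: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0),
    bootstrap_sizes: tuple[int, ...] = (1000, 5000),
    n_spiked: int = 200,
    n_genes: int = 1000,
    config: SimConfig | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    pair: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Detection power across spike-in effect sizes and bootstrap sizes.

    ``n_spiked`` genes (a minor fraction of the panel) receive a planted
    (i, n)+ effect of size beta on the standardized niche; (niche row,
    expected expression) pairs are then bootstrapped to each requested size
    and the pipeline's interaction-level sensitivity for the spiked genes
    is recorded.
    """
    base = config or SimConfig()
    fx = generate_fixture(
        SimConfig(**{**base.__dict__, "n_genes": n_genes, "seed": seed})
    )
    mu, _, p, sigma, niche_raw, niche_std, spiked = _spiked_expectation(
        fx, pair, n_spiked, 0.0, seed
    )
    rows = []
    for beta in betas:
        mu_star = apply_spikein(mu, p, niche_std.matrix, pair, spiked, beta)
        for b_size in bootstrap_sizes:
            rng_b = np.random.default_rng(seed + int(1e4 * beta) + b_size)
            niche_b, counts_b, idx = bootstrap_dataset(
                niche_raw.matrix, mu_star, b_size, rng_b, base.dispersion
            )
            ds = SpatialDataset(
                obs_ids=[f"b{j}" for j in range(b_size)],
                counts=counts_b,
                coords=fx.coords[idx],
                gene_names=list(fx.gene_names),
                sample_id="bootstrap",
            )
            comp = Composition(
                type_names=fx.type_names,
                proportions=fx.composition.proportions[idx],
                mode="proportions",
            )
            ext = [
                EffectiveNiche(
                    matrix=niche_b, bandwidth=sigma, type_names=fx.type_names
                )
            ]
            model = NicheDEModel(
                ds,
                fx.reference,
                comp,
                filters=_FIXTURE_FILTERS,
                apply_proportion_threshold=False,
                external_niches=ext,
            )
            res = model.fit()
            disc, _ = res.hierarchy(alpha)
            hit = {
                g for (g, i, n, s) in disc.triples if (i, n) == pair and s > 0
            }
            power = len(hit & set(int(g) for g in spiked)) / len(spiked)
            rows.append(
                {"beta": beta, "bootstrap_size": b_size, "power": power}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def _spiked_expectation(
    fx: Fixture,
    pair: tuple[int, int],
    n_spiked: int,
    beta: float,
    seed: int,
    sigma: float | None = None,
):
    """Shared spike-in scaffolding: truth mu, sigma, niche, spiked genes.

    The planted set is kept a minor fraction of the panel: the spots'
    observed library sizes feed the cells-per-spot estimate, so planting
    effects on most of the transcriptome would be absorbed into the offset.
    """
    mu = _truth_mu(fx)
    if sigma is None:
        sigma = _first_percentile_distance(fx.coords)
    niche_raw = compute_effective_niche(fx.coords, fx.cell_counts, sigma, fx.type_names)
    niche_std = standardize_niche(niche_raw)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (
            fx.cell_counts[:, :, None]
            * fx.reference.mean_expression[None, :, :]
            / mu[:, None, :]
        )
    p[~np.isfinite(p)] = 0.0
    p[p < 0.05] = 0.0
    rng = np.random.default_rng(seed + 7)
    spiked = rng.choice(mu.shape[1], size=n_spiked, replace=False)
    mu_star = apply_spikein(mu, p, niche_std.matrix, pair, spiked, beta)
    return mu, mu_star, p, sigma, niche_raw, niche_std, spiked


def parameter_recovery_benchmark(
    beta: float = 0.5,
    n_obs: int = 2000,
    n_genes: int = 5000,
    n_spiked: int = 200,
    config: SimConfig | None = None,
    seed: int = 0,
    pair: tuple[int, int] = (0, 1),
    ci_level: float = 0.95,
) -> dict:
    """Estimate bias and Wald-interval coverage for a planted effect.

    ``n_spiked`` genes (a minor fraction of the panel) receive the same
    planted coefficient on one (index, niche) pair; the report carries the
    mean estimate and the fraction of spiked genes whose Wald interval
    covers the truth.
    """
    base = config or SimConfig()
    fx = generate_fixture(
        SimConfig(**{**base.__dict__, "n_obs": n_obs, "n_genes": n_genes, "seed": seed})
    )
    _, mu_star, _, sigma, _, _, spiked = _spiked_expectation(
        fx, pair, n_spiked, beta, seed
    )
    counts = simulate_null_counts(mu_star, base.dispersion, np.random.default_rng(seed + 1))
    res = pipeline_on_fixture(fx, counts, bandwidths=[sigma])
    ft = res.fits[0]
    i, n = pair
    ok = ft.tested[spiked, i, n]
    est = ft.beta[spiked, i, n][ok]
    se = ft.se[spiked, i, n][ok]
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    covered = np.abs(est - beta) <= z * se
    return {
        "beta_true": beta,
        "n_genes_tested": int(ok.sum()),
        "beta_mean": float(est.mean()),
        "beta_sd": float(est.std()),
        "coverage": float(covered.mean()),
    }


# ---------------------------------------------------------------------------
# resolution degradation
# ---------------------------------------------------------------------------


def recovery_benchmark(
    sides: tuple[float, ...] = (0.9, 1.5, 2.1, 2.9),
    config: SimConfig | None = None,
    n_spiked: int = 80,
    beta: float = 1.2,
    alpha: float = 0.05,
    seed: int = 0,
    pair: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Sensitivity/specificity of niche-DE on coarsened pseudo-spot data.

    A single-cell fixture with planted effects is aggregated on square
    grids of increasing side; the discovery set at the original resolution
    is the gold standard and each coarser run is scored against it, with
    the tested universe of each run as the specificity complement.
    """
    base = config or SimConfig(resolution="single_cell", n_obs=2500, n_genes=250)
    fx = generate_fixture(SimConfig(**{**base.__dict__, "resolution": "single_cell", "seed": seed}))
    mu = fx.cell_counts @ fx.reference.mean_expression
    sigma = _first_percentile_distance(fx.coords)
    niche_raw = compute_effective_niche(fx.coords, fx.cell_counts, sigma, fx.type_names)
    niche_std = standardize_niche(niche_raw)
    p_ind = np.broadcast_to(
        fx.cell_counts[:, :, None], (mu.shape[0], len(fx.type_names), mu.shape[1])
    )
    rng = np.random.default_rng(seed + 3)
    spiked = rng.choice(mu.shape[1], size=n_spiked, replace=False)
    mu_star = apply_spikein(mu, p_ind, niche_std.matrix, pair, spiked, beta)
    counts = simulate_null_counts(mu_star, base.dispersion, rng)

    gold = None
    rows = []
    for side in sides:
        coords_a, counts_a, cells_a, spot_size = aggregate_pseudospots(
            fx.coords, counts, fx.cell_counts, side
        )
        sums = cells_a.sum(axis=1, keepdims=True)
        comp = Composition(
            type_names=fx.type_names,
            proportions=np.divide(cells_a, sums, out=np.zeros_like(cells_a), where=sums > 0),
            mode="proportions",
        )
        ds = SpatialDataset(
            obs_ids=[f"ps{j}" for j in range(counts_a.shape[0])],
            counts=counts_a,
            coords=coords_a,
            gene_names=list(fx.gene_names),
            resolution="spot",
        )
        # kernel bandwidth recomputed from each coarsened dataset's own
        # pairwise-distance distribution, as for any new dataset
        sigma_run = _first_percentile_distance(coords_a)
        model = NicheDEModel(
            ds,
            fx.reference,
            comp,
            bandwidths=[sigma_run],
            filters=_FIXTURE_FILTERS,
            apply_proportion_threshold=False,
        )
        res = model.fit()
        disc, hier = res.hierarchy(alpha)
        uni_genes = set(np.nonzero(np.isfinite(hier.pooled_gene["pos"]))[0].tolist())
        uni_pairs = {
            (int(g), int(i))
            for g, i in zip(*np.nonzero(np.isfinite(hier.pooled_celltype["pos"])))
        }
        uni_triples = {
            (int(g), int(i), int(n))
            for g, i, n in zip(*np.nonzero(np.isfinite(hier.pooled_interaction["pos"])))
        }
        if gold is None:
            gold = disc  # original-resolution run (side below the grid gap)
        reports = score_recovery(gold, disc, uni_genes, uni_pairs, uni_triples)
        for level, rep in reports.items():
            rows.append(
                {
                    "side": side,
                    "spot_size": spot_size,
                    "level": level,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ligand-receptor planted-channel recovery
# ---------------------------------------------------------------------------


def _lr_prior(
    fx: Fixture,
    rng: np.random.Generator,
    n_ligands: int = 12,
    n_targets: int = 10,
) -> tuple[LigandPrior, dict[str, list[str]]]:
    """Synthetic ligand-target prior over the fixture's genes: each ligand
    gene gets a disjoint random target block plus a matched receptor gene."""
    G = len(fx.gene_names)
    needed = n_ligands * (n_targets + 2)
    genes = rng.choice(G, size=needed, replace=False)
    ligand_names = []
    lr_pairs = []
    target_map: dict[str, list[str]] = {}
    prior = np.zeros((n_ligands, G))
    pos = 0
    for j in range(n_ligands):
        lig = fx.gene_names[genes[pos]]
        rec = fx.gene_names[genes[pos + 1]]
        targets = [fx.gene_names[t] for t in genes[pos + 2 : pos + 2 + n_targets]]
        prior[j, genes[pos + 2 : pos + 2 + n_targets]] = rng.uniform(0.5, 1.0, n_targets)
        ligand_names.append(lig)
        lr_pairs.append((lig, rec))
        target_map[lig] = targets
        pos += n_targets + 2
    return (
        LigandPrior(
            ligand_names=ligand_names,
            gene_names=list(fx.gene_names),
            ligand_target=prior,
            lr_pairs=lr_pairs,
        ),
        target_map,
    )


def lr_benchmark(
    n_replicates: int = 25,
    config: SimConfig | None = None,
    beta: float = 1.5,
    alpha: float = 0.05,
    seed: int = 0,
    pair: tuple[int, int] = (0, 1),
    planted: bool = True,
    n_targets: int = 10,
    max_candidates: int = 50,
) -> pd.DataFrame:
    """Planted ligand-receptor channel recovery (or null specificity).

    With ``planted=True``, one ligand's target block is spiked as (i, n)+
    genes, the ligand gene is made a marker of the niche type and its
    receptor a marker of the index type; the benchmark records whether the
    (ligand, receptor) pair comes out confirmed.  With ``planted=False``
    ligand/receptor genes are markers of an unrelated type, and the
    benchmark records how many chance candidates survive confirmation.
    """
    base = config or SimConfig(n_obs=600, n_genes=250)
    i_t, n_t = pair
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep in range(n_replicates):
        rep_seed = _child_seed(children[rep])
        fx = generate_fixture(SimConfig(**{**base.__dict__, "seed": rep_seed}))
        rng = np.random.default_rng(rep_seed + 11)
        prior, target_map = _lr_prior(fx, rng, n_targets=n_targets)
        lig, rec = prior.lr_pairs[0]
        gi = {g: j for j, g in enumerate(fx.gene_names)}
        A = fx.reference.mean_expression
        if planted:
            # sender expresses the ligand, receiver the receptor
            A[:, gi[lig]] = 0.02
            A[n_t, gi[lig]] = A[n_t].mean() * 5
            A[:, gi[rec]] = 0.02
            A[i_t, gi[rec]] = A[i_t].mean() * 5
        else:
            # ligands/receptors belong to a type unrelated to (i_t, n_t)
            other = next(t for t in range(len(fx.type_names)) if t not in pair)
            for l, r in prior.lr_pairs:
                A[:, gi[l]] = 0.02
                A[other, gi[l]] = A[other].mean() * 5
        mu = _truth_mu(fx)
        sigma = _first_percentile_distance(fx.coords)
        niche_raw = compute_effective_niche(fx.coords, fx.cell_counts, sigma, fx.type_names)
        niche_std = standardize_niche(niche_raw)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (
                fx.cell_counts[:, :, None]
                * fx.reference.mean_expression[None, :, :]
                / mu[:, None, :]
            )
        p[~np.isfinite(p)] = 0.0
        p[p < 0.05] = 0.0
        if planted:
            spiked = np.array([gi[t] for t in target_map[lig]])
            mu = apply_spikein(mu, p, niche_std.matrix, pair, spiked, beta)
        counts = simulate_null_counts(mu, base.dispersion, np.random.default_rng(rep_seed + 13))
        res = pipeline_on_fixture(fx, counts, bandwidths=[sigma])
        table = res.ligand_receptor(
            prior,
            fx.type_names[i_t],
            fx.type_names[n_t],
            n_targets=n_targets,
            max_candidates=max_candidates,
            alpha=alpha,
        ).table
        if planted:
            hit = bool(
                (
                    (table["ligand"] == lig)
                    & (table["receptor"] == rec)
                    & table["confirmed"]
                ).any()
            )
            rows.append({"replicate": rep, "recovered": hit})
        else:
            cand = table[table["candidate"]]
            n_cand = cand["ligand"].nunique()
            n_conf = cand[cand["confirmed"]]["ligand"].nunique()
            rows.append(
                {"replicate": rep, "n_candidates": n_cand, "n_confirmed": n_conf}
            )
    return pd.DataFrame(rows)
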