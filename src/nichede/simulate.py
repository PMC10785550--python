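"""Synthetic data generation and the benchmark designs.

The fixture generator emulates a deconvolved spot-resolution (or labelled
single-cell) spatial sample: reference profiles with type-specific markers,
spatially smoothed Dirichlet cell-type compositions so types colocalize
non-trivially, jittered-grid coordinates, and negative-binomial counts.
On top of it sit the benchmark designs: null (no niche effects), spike-in
power, SpotClean-style bleeding, bootstrap enlargement, pseudo-spot
coarsening, and recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import Composition, ReferenceProfile, SpatialDataset
from .multitest import DiscoverySet
from .niche import gaussian_kernel

__all__ = [
    "SimConfig",
    "Fixture",
    "RecoveryReport",
    "generate_fixture",
    "simulate_null_counts",
    "apply_spikein",
    "apply_bleeding",
    "bootstrap_dataset",
    "aggregate_pseudospots",
    "score_recovery",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_obs: int = 800
    n_genes: int = 300
    n_types: int = 4
    seed: int = 0
    dispersion: float = 1.0  # NB size parameter (variance mu + mu^2/size)
    mean_cells_per_spot: float = 4.0
    mean_cell_library: float = 1000.0
    marker_fold: float = 8.0
    resolution: str = "spot"
    spikein_beta: float = 0.0
    spikein_pair: tuple[int, int] = (0, 1)
    spikein_n_genes: int = 0
    bleed_alpha: float = 0.0
    bleed_tau: float | None = None  # default: 1st pairwise-distance percentile
    bootstrap_b: int = 0
    pseudospot_side: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleed_alpha <= 1.0:
            raise ValueError("bleed_alpha must lie in [0, 1]")
        if self.bootstrap_b < 0:
            raise ValueError("bootstrap size must be positive")


@dataclass
class Fixture:
    """Everything a pipeline run needs, plus the generating truth."""

    reference: ReferenceProfile
    composition: Composition
    coords: np.ndarray
    cell_counts: np.ndarray  # true n_{s,t}
    type_names: list[str]
    gene_names: list[str]
    labels: np.ndarray | None = None  # single-cell mode only
    marker_genes: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class RecoveryReport:
    level: str
    sensitivity: float
    specificity: float
    spot_size: float = np.nan


def generate_fixture(config: SimConfig) -> Fixture:
    """Draw reference profiles, compositions, and coordinates from seed.

    Reference means are log-normal with ``marker_fold``-boosted
    type-specific marker blocks; compositions come from a Dirichlet whose
    logits are smoothed mixtures of spatial bumps, so cell types form
    coherent, partially overlapping regions.  Coordinates sit on a jittered
    unit grid.  Everything is a deterministic function of the seed.
    """
    rng = np.random.default_rng(config.seed)
    S, G, T = config.n_obs, config.n_genes, config.n_types

    # coordinates: jittered square grid with unit spacing
    side = int(np.ceil(np.sqrt(S)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[:S]
    coords += rng.uniform(-0.3, 0.3, size=coords.shape)

    # reference: log-normal baseline, marker blocks boosted per type
    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    A = np.tile(base, (T, 1)) * rng.lognormal(mean=0.0, sigma=0.25, size=(T, G))
    n_markers = max(2, G // (4 * T))
    marker_genes: dict[str, list[int]] = {}
    type_names = [f"type_{t}" for t in range(T)]
    perm = rng.permutation(G)
    for t in range(T):
        block = perm[t * n_markers : (t + 1) * n_markers]
        A[t, block] *= config.marker_fold
        marker_genes[type_names[t]] = [int(g) for g in block]
    # scale each type's profile to its mean library size
    lib = np.full(T, config.mean_cell_library) * rng.uniform(0.8, 1.25, size=T)
    A = A / A.sum(axis=1, keepdims=True) * lib[:, None]
    # guarantee marker enrichment survives the noise and library scaling
    for t in range(T):
        for g in marker_genes[type_names[t]]:
            others = np.delete(A[:, g], t)
            A[t, g] = max(A[t, g], 5.0 * others.max())
    lib = A.sum(axis=1)
    reference = ReferenceProfile(
        type_names=type_names,
        mean_expression=A,
        mean_library=lib,
        gene_names=[f"gene_{g}" for g in range(G)],
    )

    # composition: spatial bumps per type -> softmax Dirichlet-like field
    n_bumps = 3
    logits = np.zeros((S, T))
    extent = coords.max(axis=0) - coords.min(axis=0)
    bump_scale = max(float(extent.max()) / 4.0, 1.0)
    for t in range(T):
        centers = coords.min(axis=0) + rng.uniform(0, 1, size=(n_bumps, 2)) * extent
        d = cdist(coords, centers)
        logits[:, t] = 2.0 * np.exp(-0.5 * (d / bump_scale) ** 2).sum(axis=1)
    logits += rng.normal(0.0, 0.4, size=logits.shape)
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    props = expl / expl.sum(axis=1, keepdims=True)

    labels = None
    if config.resolution == "single_cell":
        labels = np.array([rng.choice(T, p=props[s]) for s in range(S)])
        indic = np.zeros((S, T))
        indic[np.arange(S), labels] = 1.0
        composition = Composition(
            type_names=type_names, proportions=indic, mode="labels"
        )
        cell_counts = indic
    else:
        # integer-ish cell counts: N_s cells multinomially split by proportions
        n_cells = rng.poisson(config.mean_cells_per_spot - 1, size=S) + 1
        cell_counts = np.vstack(
            [rng.multinomial(n, props[s]) for s, n in enumerate(n_cells)]
        ).astype(float)
        sums = cell_counts.sum(axis=1, keepdims=True)
        composition = Composition(
            type_names=type_names, proportions=cell_counts / sums, mode="proportions"
        )
    return Fixture(
        reference=reference,
        composition=composition,
        coords=coords,
        cell_counts=cell_counts,
        type_names=type_names,
        gene_names=reference.gene_names,
        labels=labels,
        marker_genes=marker_genes,
    )


def simulate_null_counts(
    mu: np.ndarray, dispersion: float | np.ndarray = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Independent NB draws per entry: mean mu, variance mu + mu^2/size.

    ``dispersion`` is the NB size parameter (scalar or per-gene); entries
    with mu = 0 are exactly 0.  There is no dependence between neighbors,
    so data drawn this way contain no niche effects.
    """
    rng = rng or np.random.default_rng(0)
    mu = np.asarray(mu, dtype=float)
    size = np.broadcast_to(np.asarray(dispersion, dtype=float), mu.shape[-1:])
    size_full = np.broadcast_to(size, mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = size_full[pos] / (size_full[pos] + mu[pos])
    out[pos] = rng.negative_binomial(size_full[pos], p)
    return out


def apply_spikein(
    mu: np.ndarray,
    p: np.ndarray,
    niche_std: np.ndarray,
    pair: tuple[int, int],
    genes: np.ndarray,
    beta: float,
) -> np.ndarray:
    """Plant a niche effect: mu* = mu * exp(p_{s,i,g} * beta * N_{s,n})
    for the selected genes; all other genes are untouched."""
    i, n = pair
    mu_star = np.asarray(mu, dtype=float).copy()
    genes = np.asarray(genes, dtype=int)
    factor = np.exp(p[:, i, genes] * beta * niche_std[:, [n]])
    mu_star[:, genes] = mu_star[:, genes] * factor
    return mu_star


def apply_bleeding(
    mu: np.ndarray,
    alpha: float | np.ndarray,
    tau: float,
    coords: np.ndarray,
) -> np.ndarray:
    """SpotClean-style contamination with a destination-normalized kernel.

    A fraction ``alpha`` (scalar or per-gene) of each source spot's expected
    expression is redistributed to all spots in proportion to
    K_tau(s, s') / sum_{s''} K_tau(s', s''), which conserves each gene's
    total expected count exactly.
    """
    if tau <= 0:
        raise ValueError("bleeding bandwidth tau must be positive")
    mu = np.asarray(mu, dtype=float)
    K = gaussian_kernel(cdist(coords, coords), tau)
    W = K / K.sum(axis=0, keepdims=True)  # column s': distribution over destinations
    alpha_g = np.broadcast_to(np.asarray(alpha, dtype=float), (mu.shape[1],))
    return (1.0 - alpha_g[None, :]) * mu + alpha_g[None, :] * (W @ mu)


def bootstrap_dataset(
    niche: np.ndarray,
    mu: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    dispersion: float | np.ndarray = 1.0,
    indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample (niche row, expected-expression row) pairs with replacement
    to ``n_samples`` rows and redraw NB counts per sampled row.

    Returns (resampled niche, redrawn counts, resample indices); explicit
    ``indices`` force a particular resample (used for identity checks).
    """
    S = mu.shape[0]
    if indices is None:
        indices = rng.integers(0, S, size=n_samples)
    else:
        indices = np.asarray(indices, dtype=int)
    mu_b = mu[indices]
    counts_b = simulate_null_counts(mu_b, dispersion, rng)
    return niche[indices], counts_b, indices


def aggregate_pseudospots(
    coords: np.ndarray,
    counts: np.ndarray,
    cell_counts: np.ndarray,
    side: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Aggregate observations on a square grid of the given side length.

    Counts and cell counts are summed within squares; the pseudo-spot
    coordinate is the square center.  Returns (coords, counts, cell_counts,
    spot_size) where spot_size is the mean number of original observations
    per nonempty square.
    """
    if side <= 0:
        raise ValueError("square side must be positive")
    coords = np.asarray(coords, dtype=float)
    origin = coords.min(axis=0)
    bins = np.floor((coords - origin) / side).astype(int)
    keys, inverse = np.unique(bins, axis=0, return_inverse=True)
    n_sq = keys.shape[0]
    counts_new = np.zeros((n_sq, counts.shape[1]), dtype=counts.dtype)
    cells_new = np.zeros((n_sq, cell_counts.shape[1]))
    np.add.at(counts_new, inverse, counts)
    np.add.at(cells_new, inverse, cell_counts)
    coords_new = origin + (keys + 0.5) * side
    spot_size = coords.shape[0] / n_sq
    return coords_new, counts_new, cells_new, float(spot_size)


def score_recovery(
    gold: DiscoverySet,
    test: DiscoverySet,
    universe_genes: set[int],
    universe_pairs: set[tuple[int, int]],
    universe_triples: set[tuple[int, int, int]],
) -> dict[str, RecoveryReport]:
    """Sensitivity and specificity per level against a gold-standard set.

    Sensitivity = |test AND gold| / |gold|; specificity is computed on the
    complement of gold within the declared tested universe of each level.
    Empty gold (or empty complement) yields NaN for the affected rate.
    """

    def rates(gold_s: set, test_s: set, universe: set) -> tuple[float, float]:
        sens = len(test_s & gold_s) / len(gold_s) if gold_s else np.nan
        comp = universe - gold_s
        spec = len(comp - test_s) / len(comp) if comp else np.nan
        return sens, spec

    out = {}
    for level, g_set, t_set, uni in (
        ("gene", gold.genes, test.genes, universe_genes),
        ("cell_type", gold.pairs, test.pairs, universe_pairs),
        ("interaction", gold.triples_unsigned(), test.triples_unsigned(), universe_triples),
    ):
        sens, spec = rates(g_set, t_set, uni)
        out[level] = RecoveryReport(level=level, sensitivity=sens, specificity=spec)
    return out
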