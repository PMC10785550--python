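"""Effective-niche computation, standardization, and cross-sample harmonization.

The effective niche of an observation is the kernel-weighted count of each
cell type in its spatial neighborhood,

    N_{sigma, s, t} = sum_{s'} K_sigma(d(s, s')) * n_{s', t},

with a Gaussian kernel K_sigma(d) = phi(d / sigma) / sigma and Euclidean
distances.  The sum runs over all observations including s itself; a flag
allows excluding the self term for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "EffectiveNiche",
    "gaussian_kernel",
    "compute_effective_niche",
    "standardize_niche",
    "harmonize_scale_factor",
    "harmonize_samples",
    "default_bandwidths",
]

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass
class EffectiveNiche:
    """Observation x cell-type kernel-smoothed neighborhood composition."""

    matrix: np.ndarray
    bandwidth: float
    type_names: list[str]
    standardized: bool = False
    column_stats: np.ndarray | None = None  # (2, T): means and sds used
    excluded_types: list[int] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]


def gaussian_kernel(d: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """Gaussian kernel weight ``phi(d / sigma) / sigma`` for distance ``d``."""
    if sigma <= 0:
        raise ValueError(f"bandwidth must be positive, got {sigma}")
    z = np.asarray(d, dtype=float) / sigma
    w = _INV_SQRT_2PI * np.exp(-0.5 * z * z) / sigma
    if np.isscalar(d):
        return float(w)
    return w


def compute_effective_niche(
    coords: np.ndarray,
    cell_counts: np.ndarray,
    sigma: float,
    type_names: list[str] | None = None,
    include_self: bool = True,
) -> EffectiveNiche:
    """Kernel-smooth per-observation cell-type counts over space.

    Parameters
    ----------
    coords
        Observations x 2 positions.
    cell_counts
        Observations x types matrix ``n_{s,t}``: indicators at single-cell
        resolution, estimated cell counts for spots.
    sigma
        Kernel bandwidth in coordinate units.
    include_self
        Whether the index observation's own composition contributes
        ``K_sigma(0) * n_{s,t}`` to its niche (the definition sums over all
        observations; ``False`` drops the self term).
    """
    coords = np.asarray(coords, dtype=float)
    cell_counts = np.asarray(cell_counts, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty dataset")
    if coords.shape[0] != cell_counts.shape[0]:
        raise ValueError("coords and cell counts are misaligned")
    weights = gaussian_kernel(cdist(coords, coords), sigma)
    if not include_self:
        np.fill_diagonal(weights, 0.0)
    matrix = weights @ cell_counts
    if type_names is None:
        type_names = [f"type_{j}" for j in range(cell_counts.shape[1])]
    return EffectiveNiche(matrix=matrix, bandwidth=float(sigma), type_names=list(type_names))


def standardize_niche(niche: EffectiveNiche) -> EffectiveNiche:
    """Scale each niche column to mean 0, sd 1.

    Zero-variance columns cannot be standardized; they are left at 0 and
    recorded in ``excluded_types`` so the regression fixes their
    coefficients at zero.  Applying the operation to already-standardized
    input is a no-op up to floating point.
    """
    mat = niche.matrix.astype(float)
    means = mat.mean(axis=0)
    sds = mat.std(axis=0)
    excluded = [int(j) for j in np.nonzero(sds == 0)[0]]
    safe_sd = np.where(sds == 0, 1.0, sds)
    out = (mat - means) / safe_sd
    out[:, excluded] = 0.0
    return EffectiveNiche(
        matrix=out,
        bandwidth=niche.bandwidth,
        type_names=niche.type_names,
        standardized=True,
        column_stats=np.vstack([means, sds]),
        excluded_types=excluded,
    )


def harmonize_scale_factor(
    spot_radius_ref: float,
    spot_radius_query: float,
    mean_cells_ref: float,
    mean_cells_query: float,
) -> float:
    """Scale factor (N_r * q^2) / (N_q * r^2) applied to a query niche.

    The N_r/N_q term corrects for sequencing-depth differences between the
    reference and query samples; q^2/r^2 corrects for spot-area differences.
    """
    if spot_radius_ref <= 0 or spot_radius_query <= 0:
        raise ValueError("spot radii must be positive")
    return (mean_cells_ref * spot_radius_query**2) / (
        mean_cells_query * spot_radius_ref**2
    )


def harmonize_samples(
    niches: list[EffectiveNiche],
    sample_ids: list[str],
    reference_sample: str,
    spot_radii: dict[str, float] | None = None,
    mean_cells: dict[str, float] | None = None,
) -> tuple[EffectiveNiche, np.ndarray]:
    """Stack per-sample niches onto a common scale with batch labels.

    Query niches are multiplied by :func:`harmonize_scale_factor` relative
    to the designated reference sample; the returned label array provides
    per-sample intercepts for the regression.  When radii / mean cell
    numbers are not given (single-cell data), scaling is skipped.
    """
    if reference_sample not in sample_ids:
        raise ValueError(f"reference sample {reference_sample!r} not in samples")
    if len(niches) != len(sample_ids):
        raise ValueError("one niche per sample required")
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for niche, sid in zip(niches, sample_ids):
        mat = niche.matrix
        if spot_radii is not None and mean_cells is not None:
            if sid not in spot_radii or sid not in mean_cells:
                raise ValueError(f"missing radius or mean-cell count for sample {sid!r}")
            factor = harmonize_scale_factor(
                spot_radii[reference_sample],
                spot_radii[sid],
                mean_cells[reference_sample],
                mean_cells[sid],
            )
            mat = mat * factor
        blocks.append(mat)
        labels.append(np.repeat(sid, mat.shape[0]))
    pooled = EffectiveNiche(
        matrix=np.vstack(blocks),
        bandwidth=niches[0].bandwidth,
        type_names=niches[0].type_names,
    )
    return pooled, np.concatenate(labels)


def default_bandwidths(
    coords: np.ndarray,
    percentiles: tuple[float, ...] = (1.0, 5.0, 10.0),
    max_subsample: int = 2000,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Bandwidth grid at percentiles of the pairwise-distance distribution.

    Percentiles are estimated from at most ``max_subsample`` observations for
    tractability on large samples.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n > max_subsample:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(n, size=max_subsample, replace=False)
        coords = coords[idx]
    d = cdist(coords, coords)
    upper = d[np.triu_indices_from(d, k=1)]
    vals = np.percentile(upper, percentiles)
    return [float(max(v, 1e-12)) for v in vals]
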