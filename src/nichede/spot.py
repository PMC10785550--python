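"""Spot-level model ingredients derived from composition and reference.

Given deconvolution proportions pi_{s,t} and a reference profile with
per-type mean expression A_{t,g} and mean library sizes L_t, this module
derives the quantities entering the regression: estimated cells per spot
N_hat_s, expected spot expression mu_{s,g}, and the expression-source
proportions p_{s,t,g}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Composition, ReferenceProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SpotExpectation",
    "estimate_cells_per_spot",
    "expected_spot_expression",
    "expression_proportions",
    "scale_singlecell_means",
    "cap_counts",
    "threshold_proportions",
]


@dataclass
class SpotExpectation:
    """Expected expression and expression-source proportions per spot."""

    mu: np.ndarray  # (S, G)
    p: np.ndarray  # (S, T, G)
    cells_per_spot: np.ndarray  # (S,)
    cell_counts: np.ndarray  # (S, T) n_{s,t}


def estimate_cells_per_spot(
    observed_library: np.ndarray,
    proportions: np.ndarray,
    mean_library: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate cells per spot and per-type cell counts.

    ``N_hat_s = L_s / sum_t pi_{s,t} L_t`` and ``n_{s,t} = N_hat_s pi_{s,t}``.
    All-zero proportion rows cannot be calibrated; they get ``N_hat = 0``
    (the observation is excluded downstream) with a log entry.
    """
    observed_library = np.asarray(observed_library, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    mean_library = np.asarray(mean_library, dtype=float)
    denom = proportions @ mean_library
    zero = denom <= 0
    if np.any(zero):
        logger.info("excluding %d observations with all-zero composition", int(zero.sum()))
    n_hat = np.where(zero, 0.0, observed_library / np.where(zero, 1.0, denom))
    cell_counts = n_hat[:, None] * proportions
    return n_hat, cell_counts


def expected_spot_expression(cell_counts: np.ndarray, mean_expression: np.ndarray) -> np.ndarray:
    """mu_{s,g} = sum_t n_{s,t} A_{t,g} (linear in the cell counts)."""
    return np.asarray(cell_counts, dtype=float) @ np.asarray(mean_expression, dtype=float)


def expression_proportions(
    cell_counts: np.ndarray,
    mean_expression: np.ndarray,
    mu: np.ndarray | None = None,
    threshold: float = 0.05,
) -> np.ndarray:
    """Expected proportion of each spot-gene's expression per source type.

    ``p_{s,t,g} = n_{s,t} A_{t,g} / mu_{s,g}``; entries below ``threshold``
    are zeroed for numerical stability and the remainder is *not*
    renormalized.  Spots with ``mu_{s,g} = 0`` get all-zero proportions for
    that gene.
    """
    cell_counts = np.asarray(cell_counts, dtype=float)
    A = np.asarray(mean_expression, dtype=float)
    if mu is None:
        mu = expected_spot_expression(cell_counts, A)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = cell_counts[:, :, None] * A[None, :, :] / mu[:, None, :]
    p[~np.isfinite(p)] = 0.0
    p[p < threshold] = 0.0
    return p


def scale_singlecell_means(
    mean_expression: np.ndarray,
    labels: np.ndarray,
    cell_library: np.ndarray,
    mean_library: np.ndarray,
) -> np.ndarray:
    """Per-cell expected expression mu_{c,g} = A_{T_c,g} * L_c / L_{T_c}.

    Cells of the same type differ in sequencing depth; scaling the reference
    row by the cell's relative library size keeps depth patterns from
    masquerading as niche effects.  Cells with zero library get a zero row
    and are excluded from the regression downstream.
    """
    labels = np.asarray(labels, dtype=int)
    scale = np.asarray(cell_library, dtype=float) / np.asarray(mean_library, dtype=float)[labels]
    return np.asarray(mean_expression, dtype=float)[labels] * scale[:, None]


def cap_counts(counts: np.ndarray, percentile: float = 99.5) -> np.ndarray:
    """Cap each gene's counts at its empirical percentile across observations.

    The cap uses the linear-interpolation empirical quantile, rounded down to
    an integer so capped values remain valid counts.
    """
    counts = np.asarray(counts)
    caps = np.floor(np.percentile(counts, percentile, axis=0)).astype(counts.dtype)
    return np.minimum(counts, caps[None, :])


def threshold_proportions(
    composition: Composition,
    min_proportion: float = 0.05,
    per_type_min: dict[str, float] | None = None,
) -> Composition:
    """Zero out small deconvolution proportions and renormalize rows.

    ``min_proportion`` applies to every type; ``per_type_min`` overrides it
    per type (types failing their override are set to 0 entirely).  Rows
    that end up all-zero stay all-zero and are excluded downstream.
    """
    props = composition.proportions.copy()
    mins = np.full(props.shape[1], float(min_proportion))
    if per_type_min:
        for t, v in per_type_min.items():
            if t not in composition.type_names:
                raise ValueError(f"unknown cell-type name {t!r}")
            mins[composition.type_names.index(t)] = float(v)
    props[props < mins[None, :]] = 0.0
    sums = props.sum(axis=1)
    nz = sums > 0
    props[nz] = props[nz] / sums[nz, None]
    return Composition(
        type_names=composition.type_names, proportions=props, mode=composition.mode
    )
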