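"""Readers, writers, and the dataset containers shared by every stage.

All observation alignment is by identifier, never by row position.  Matrix
Market triplet files are 1-based on disk and converted to 0-based indices at
this boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialDataset",
    "ReferenceProfile",
    "Composition",
    "LigandPrior",
    "FormatError",
    "read_counts",
    "read_coordinates",
    "read_reference",
    "read_composition",
    "read_ligand_prior",
    "write_counts",
    "write_coordinates",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpatialDataset:
    """Counts, coordinates and names for one spatial sample.

    Parameters
    ----------
    obs_ids
        Unique observation (cell or spot) identifiers.
    counts
        Observations x genes matrix of non-negative integer counts.
    coords
        Observations x 2 array of (x, y) positions, row-aligned with
        ``counts``.  Units are "pixels"; ``units_per_pixel`` records the
        physical scale when known.
    gene_names
        Unique gene names, column-aligned with ``counts``.
    sample_id
        Label used for batch bookkeeping in multi-sample analyses.
    resolution
        ``"single_cell"`` when each observation is one labelled cell,
        ``"spot"`` when it is a mixture of cells.
    """

    obs_ids: list[str]
    counts: np.ndarray
    coords: np.ndarray | None = None
    gene_names: list[str] = field(default_factory=list)
    sample_id: str = "sample"
    resolution: str = "spot"
    units_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.all(np.isfinite(self.counts)):
            raise FormatError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise FormatError("negative count")
        if len(self.obs_ids) != self.counts.shape[0]:
            raise FormatError(
                f"{len(self.obs_ids)} observation ids for "
                f"{self.counts.shape[0]} count rows"
            )
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise FormatError("duplicate observation ids")
        if self.gene_names:
            if len(self.gene_names) != self.counts.shape[1]:
                raise FormatError("gene name count does not match columns")
            if len(set(self.gene_names)) != len(self.gene_names):
                raise FormatError("duplicate gene names")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.counts.shape[0], 2):
                raise FormatError("coords must be observations x 2")
        if self.resolution not in ("single_cell", "spot"):
            raise FormatError(f"unknown resolution {self.resolution!r}")

    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Observed library size per observation (row sums)."""
        return self.counts.sum(axis=1).astype(float)


@dataclass
class ReferenceProfile:
    """Cell-type mean expression profiles and mean library sizes.

    ``mean_expression[t, g]`` is the expected count of gene ``g`` in an
    average cell of type ``t``; ``mean_library[t]`` is the average library
    size of that type.
    """

    type_names: list[str]
    mean_expression: np.ndarray
    mean_library: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean_expression = np.asarray(self.mean_expression, dtype=float)
        self.mean_library = np.asarray(self.mean_library, dtype=float)
        if np.any(self.mean_expression < 0):
            raise FormatError("reference mean expression must be >= 0")
        if np.any(self.mean_library <= 0):
            raise FormatError("reference mean library sizes must be > 0")
        if len(set(self.type_names)) != len(self.type_names):
            raise FormatError("duplicate cell-type names")
        if self.mean_expression.shape[0] != len(self.type_names):
            raise FormatError("type names do not match expression rows")
        if self.gene_names and len(self.gene_names) != self.mean_expression.shape[1]:
            raise FormatError("gene names do not match expression columns")

    @property
    def n_types(self) -> int:
        return len(self.type_names)


@dataclass
class Composition:
    """Per-observation cell-type composition.

    ``mode="labels"`` encodes single-cell hard labels as indicator rows;
    ``mode="proportions"`` stores deconvolution proportions.  ``cell_counts``
    holds estimated cells of each type per observation (indicators at
    single-cell resolution) and is filled in by the spot model.
    """

    type_names: list[str]
    proportions: np.ndarray
    mode: str = "proportions"
    cell_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.mode not in ("labels", "proportions"):
            raise FormatError(f"unknown composition mode {self.mode!r}")
        if np.any(self.proportions < 0):
            raise FormatError("negative composition entry")
        sums = self.proportions.sum(axis=1)
        bad = ~(np.isclose(sums, 1.0, atol=1e-8) | np.isclose(sums, 0.0, atol=1e-12))
        if np.any(bad):
            i = int(np.nonzero(bad)[0][0])
            raise FormatError(f"row sum {sums[i]:g} in composition row {i}")
        if self.mode == "labels":
            is_indicator = np.all(np.isin(self.proportions, (0.0, 1.0)))
            if not is_indicator:
                raise FormatError("labels mode requires indicator rows")
        if self.cell_counts is not None:
            self.cell_counts = np.asarray(self.cell_counts, dtype=float)
            if np.any(self.cell_counts < 0):
                raise FormatError("negative cell counts")

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    @classmethod
    def from_labels(cls, labels: list[str], type_names: list[str]) -> "Composition":
        """Build an indicator composition from hard cell-type labels."""
        index = {t: j for j, t in enumerate(type_names)}
        unknown = sorted({l for l in labels if l not in index})
        if unknown:
            raise FormatError(f"unknown cell-type name(s): {', '.join(unknown)}")
        mat = np.zeros((len(labels), len(type_names)))
        for i, lab in enumerate(labels):
            mat[i, index[lab]] = 1.0
        return cls(type_names=type_names, proportions=mat, mode="labels")


@dataclass
class LigandPrior:
    """Ligand-target prior matrix plus known ligand-receptor pairs."""

    ligand_names: list[str]
    gene_names: list[str]
    ligand_target: np.ndarray
    lr_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.ligand_target = np.asarray(self.ligand_target, dtype=float)
        if np.any(self.ligand_target < 0):
            raise FormatError("ligand-target prior must be >= 0")
        if self.ligand_target.shape != (len(self.ligand_names), len(self.gene_names)):
            raise FormatError("ligand-target shape does not match names")

    def receptors_of(self, ligand: str) -> list[str]:
        return [r for (l, r) in self.lr_pairs if l == ligand]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, fmt: str = "delimited") -> SpatialDataset:
    """Read a counts matrix into a :class:`SpatialDataset` (names only).

    ``fmt="mtx_triplet"`` expects a 10x-style trio: ``<stem>.mtx`` plus
    ``barcodes.tsv`` and ``features.tsv`` next to it (observations as rows).
    ``fmt="delimited"`` expects a table with observation ids in the first
    column and gene names in the header.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"counts file not found: {path}")
    if fmt == "mtx_triplet":
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy message passthrough
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = sparse.coo_matrix(mat)
        if np.any(mat.data < 0):
            raise FormatError("negative count in Matrix Market data")
        barcodes = path.parent / "barcodes.tsv"
        features = path.parent / "features.tsv"
        for companion in (barcodes, features):
            if not companion.exists():
                raise FormatError(f"missing companion file {companion}")
        obs_ids = barcodes.read_text().split()
        gene_names = features.read_text().split()
        dense = np.asarray(mat.todense())
        if dense.shape != (len(obs_ids), len(gene_names)):
            raise FormatError(
                f"matrix shape {dense.shape} does not match "
                f"{len(obs_ids)} barcodes x {len(gene_names)} features"
            )
        counts = dense
    elif fmt == "delimited":
        # pandas silently renames duplicate header fields; check them raw
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        delim = "\t" if "\t" in header else ("," if "," in header else None)
        if delim is not None:
            names = header.split(delim)[1:]
            if len(set(names)) != len(names):
                raise FormatError("duplicate gene names in counts header")
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if df.isna().any().any():
            raise FormatError(f"missing values in counts table {path}")
        counts = df.to_numpy()
        if np.any(counts < 0):
            raise FormatError("negative count in counts table")
        obs_ids = [str(i) for i in df.index]
        gene_names = [str(c) for c in df.columns]
    else:
        raise FormatError(f"unknown counts format {fmt!r}")
    if not np.allclose(counts, np.round(counts)):
        raise FormatError("counts must be integers")
    return SpatialDataset(
        obs_ids=list(obs_ids),
        counts=np.round(counts).astype(np.int64),
        gene_names=list(gene_names),
    )


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read an (id, x, y) coordinate table keyed by observation id."""
    with open(path) as fh:
        header = fh.readline()
    delim = "\t" if "\t" in header else ","
    # round_trip parsing: coordinates must survive write/read bit-exactly
    df = pd.read_csv(path, sep=delim, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("id", "x", "y") if c not in cols]
    if missing:
        raise FormatError(f"coordinate table missing column(s): {missing}")
    out = df[[cols["id"], cols["x"], cols["y"]]].copy()
    out.columns = ["id", "x", "y"]
    out["id"] = out["id"].astype(str)
    for c in ("x", "y"):
        try:
            out[c] = pd.to_numeric(out[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric coordinate in column {c}") from exc
    if out["id"].duplicated().any():
        raise FormatError("duplicate observation ids in coordinates")
    return out.set_index("id")


def attach_coordinates(dataset: SpatialDataset, coords: pd.DataFrame) -> SpatialDataset:
    """Align a coordinate table to a dataset by exact id match."""
    orphans = sorted(set(coords.index) - set(dataset.obs_ids))
    if orphans:
        raise FormatError(f"coordinate ids absent from counts: {orphans[:10]}")
    missing = sorted(set(dataset.obs_ids) - set(coords.index))
    if missing:
        raise FormatError(f"observations without coordinates: {missing[:10]}")
    dataset.coords = coords.loc[dataset.obs_ids, ["x", "y"]].to_numpy(dtype=float)
    return dataset


def read_reference(path: str | Path) -> ReferenceProfile:
    """Read a types x genes reference CSV with a ``library_size`` column."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if "library_size" not in df.columns:
        raise FormatError("reference table must include a library_size column")
    lib = df.pop("library_size").to_numpy(dtype=float)
    return ReferenceProfile(
        type_names=[str(t) for t in df.index],
        mean_expression=df.to_numpy(dtype=float),
        mean_library=lib,
        gene_names=[str(g) for g in df.columns],
    )


def read_composition(path: str | Path, mode: str = "proportions") -> Composition:
    """Read per-observation composition; ``mode="labels"`` expects a
    two-column (id, label) table, otherwise an observations x types table."""
    if mode == "labels":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise FormatError("label table needs id and label columns")
        labels = [str(v) for v in df.iloc[:, 1]]
        type_names = sorted(set(labels))
        comp = Composition.from_labels(labels, type_names)
        comp.obs_ids = [str(v) for v in df.iloc[:, 0]]  # type: ignore[attr-defined]
        return comp
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    comp = Composition(
        type_names=[str(c) for c in df.columns],
        proportions=df.to_numpy(dtype=float),
        mode="proportions",
    )
    comp.obs_ids = [str(i) for i in df.index]  # type: ignore[attr-defined]
    return comp


def read_ligand_prior(path_matrix: str | Path, path_pairs: str | Path) -> LigandPrior:
    """Read a ligands x genes prior CSV and a (ligand, receptor) pair CSV."""
    mat = pd.read_csv(path_matrix, sep=None, engine="python", index_col=0)
    pairs_df = pd.read_csv(path_pairs, sep=None, engine="python")
    cols = {c.lower(): c for c in pairs_df.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise FormatError("LR pair table needs ligand and receptor columns")
    pairs = [
        (str(l), str(r))
        for l, r in zip(pairs_df[cols["ligand"]], pairs_df[cols["receptor"]])
    ]
    genes = [str(g) for g in mat.columns]
    gene_set = set(genes)
    bad = sorted({r for (_, r) in pairs if r not in gene_set})
    if bad:
        logger.warning("receptors absent from prior gene set: %s", bad[:10])
    return LigandPrior(
        ligand_names=[str(l) for l in mat.index],
        gene_names=genes,
        ligand_target=mat.to_numpy(dtype=float),
        lr_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_counts(dataset: SpatialDataset, path: str | Path, fmt: str = "delimited") -> None:
    path = Path(path)
    if fmt == "mtx_triplet":
        spio.mmwrite(path, sparse.coo_matrix(dataset.counts))
        (path.parent / "barcodes.tsv").write_text("\n".join(dataset.obs_ids) + "\n")
        (path.parent / "features.tsv").write_text("\n".join(dataset.gene_names) + "\n")
    elif fmt == "delimited":
        pd.DataFrame(
            dataset.counts, index=dataset.obs_ids, columns=dataset.gene_names
        ).to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown counts format {fmt!r}")


def write_coordinates(dataset: SpatialDataset, path: str | Path) -> None:
    if dataset.coords is None:
        raise FormatError("dataset has no coordinates")
    pd.DataFrame(
        {"id": dataset.obs_ids, "x": dataset.coords[:, 0], "y": dataset.coords[:, 1]}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV in deterministic lexicographic order.

    Rows are sorted by whichever of (gene, index_type, niche_type) are
    present; floats are written with 12 significant digits so a write/read
    round trip is lossless at that precision.
    """
    path = Path(path)
    sort_cols = [c for c in ("gene", "index_type", "niche_type") if c in table.columns]
    if sort_cols:
        table = table.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def intersect_genes(
    dataset: SpatialDataset, reference: ReferenceProfile
) -> tuple[SpatialDataset, ReferenceProfile]:
    """Restrict both objects to their exact-string gene intersection."""
    shared = [g for g in dataset.gene_names if g in set(reference.gene_names)]
    dropped = dataset.n_genes - len(shared)
    if dropped:
        logger.info("dropping %d genes absent from the reference", dropped)
    if not shared:
        raise FormatError("no genes shared between counts and reference")
    dcols = [dataset.gene_names.index(g) for g in shared]
    rcols = [reference.gene_names.index(g) for g in shared]
    new_ds = SpatialDataset(
        obs_ids=dataset.obs_ids,
        counts=dataset.counts[:, dcols],
        coords=dataset.coords,
        gene_names=shared,
        sample_id=dataset.sample_id,
        resolution=dataset.resolution,
        units_per_pixel=dataset.units_per_pixel,
    )
    new_ref = ReferenceProfile(
        type_names=reference.type_names,
        mean_expression=reference.mean_expression[:, rcols],
        mean_library=reference.mean_library,
        gene_names=shared,
    )
    return new_ds, new_ref
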