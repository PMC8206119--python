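"""Shared data model for allele-resolved single-cell UMI count data.

The central container is :class:`AllelicCountSet`: five genes x cells UMI
count layers (a non-allelic total plus spliced/unspliced counts split by the
B6 and Cast alleles of an F1 hybrid), a gene annotation table and a cell
metadata table.  Allele-assignable molecules (those covering a strain SNP)
are a small subset of all molecules, so the allelic spliced layers must sum
to at most the total layer element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Canonical layer names, in on-disk order.
LAYER_NAMES = ("total", "spliced_B6", "spliced_Cast", "unspliced_B6", "unspliced_Cast")

#: Required gene annotation columns.
GENE_COLUMNS = ("gene_id", "name", "chromosome", "start", "end", "is_pseudogene")

#: Required cell metadata columns (additional QC columns are preserved as-is).
CELL_COLUMNS = ("cell_id", "time_point_days")

X_CHROMOSOME = "chrX"
XIST_GENE_NAME = "Xist"


def _as_csr(mat) -> sp.csr_matrix:
    m = sp.csr_matrix(mat)
    m.sum_duplicates()
    m.sort_indices()
    return m


@dataclass
class AllelicCountSet:
    """Genes x cells UMI counts in five layers plus annotation tables.

    Parameters
    ----------
    genes
        One row per gene; columns ``gene_id, name, chromosome, start, end,
        is_pseudogene``.  Coordinates are 1-based inclusive (mm10-style).
    cells
        One row per cell; columns ``cell_id, time_point_days`` plus optional
        QC metrics (``n_reads``, ``n_umi``, ``n_genes``, ``pct_mito``,
        ``pct_ercc``, ``dead_stain_intensity``, ...).
    layers
        Mapping from :data:`LAYER_NAMES` to sparse integer matrices of shape
        ``(n_genes, n_cells)``.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame
    layers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genes = self.genes.reset_index(drop=True)
        self.cells = self.cells.reset_index(drop=True)
        self.layers = {k: _as_csr(v) for k, v in self.layers.items()}

    # ------------------------------------------------------------------ views
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def layer(self, name: str) -> sp.csr_matrix:
        return self.layers[name]

    def dense(self, name: str) -> np.ndarray:
        return np.asarray(self.layers[name].todense())

    def x_gene_mask(self, exclude_xist: bool = True) -> np.ndarray:
        """Boolean mask over genes on the X chromosome."""
        mask = (self.genes["chromosome"] == X_CHROMOSOME).to_numpy()
        if exclude_xist:
            mask &= (self.genes["name"] != XIST_GENE_NAME).to_numpy()
        return mask

    def autosomal_gene_mask(self) -> np.ndarray:
        chrom = self.genes["chromosome"].astype(str)
        return (~chrom.isin([X_CHROMOSOME, "chrY", "chrM"])).to_numpy()

    def xist_index(self) -> int:
        idx = np.flatnonzero((self.genes["name"] == XIST_GENE_NAME).to_numpy())
        if idx.size == 0:
            raise ValueError("dataset contains no gene named 'Xist'")
        return int(idx[0])

    def xist_counts(self, layer: str = "total") -> np.ndarray:
        """Per-cell UMI counts of the Xist gene from the requested layer."""
        return self.dense(layer)[self.xist_index()]

    # --------------------------------------------------------------- subsets
    def subset(self, gene_mask=None, cell_mask=None) -> "AllelicCountSet":
        gm = np.asarray(gene_mask) if gene_mask is not None else np.ones(self.n_genes, bool)
        cm = np.asarray(cell_mask) if cell_mask is not None else np.ones(self.n_cells, bool)
        if gm.dtype != bool:
            tmp = np.zeros(self.n_genes, bool)
            tmp[gm] = True
            gm = tmp
        if cm.dtype != bool:
            tmp = np.zeros(self.n_cells, bool)
            tmp[cm] = True
            cm = tmp
        layers = {k: v[gm][:, cm] for k, v in self.layers.items()}
        return AllelicCountSet(self.genes.loc[gm].copy(), self.cells.loc[cm].copy(), layers)

    def copy(self) -> "AllelicCountSet":
        return AllelicCountSet(
            self.genes.copy(), self.cells.copy(), {k: v.copy() for k, v in self.layers.items()}
        )

    def equals(self, other: "AllelicCountSet") -> bool:
        if set(self.layers) != set(other.layers):
            return False
        for k in self.layers:
            if (self.layers[k] != other.layers[k]).nnz != 0:
                return False
        a, b = self.genes.reset_index(drop=True), other.genes.reset_index(drop=True)
        c, d = self.cells.reset_index(drop=True), other.cells.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
            pd.testing.assert_frame_equal(c, d, check_dtype=False)
        except AssertionError:
            return False
        return True


def validate_dataset(dataset: AllelicCountSet) -> list:
    """Check every container invariant; return a list of violation messages.

    Validation is total: it reports problems and never raises on a
    syntactically well-formed container.
    """
    violations = []
    for name in LAYER_NAMES:
        if name not in dataset.layers:
            violations.append(f"missing layer: {name}")
    shapes = {k: v.shape for k, v in dataset.layers.items()}
    expected = (dataset.n_genes, dataset.n_cells)
    for k, shape in shapes.items():
        if shape != expected:
            violations.append(f"layer {k} has shape {shape}, expected {expected}")
    for col in GENE_COLUMNS:
        if col not in dataset.genes.columns:
            violations.append(f"genes table missing column: {col}")
    for col in CELL_COLUMNS:
        if col not in dataset.cells.columns:
            violations.append(f"cells table missing column: {col}")
    for k, v in dataset.layers.items():
        if v.nnz and v.data.min() < 0:
            g, c = _first_offender(v, lambda d: d < 0)
            violations.append(f"layer {k} has negative count at gene index {g}, cell index {c}")
        if v.nnz and np.any(v.data != np.round(v.data)):
            violations.append(f"layer {k} has non-integer entries")
    if (
        all(n in dataset.layers for n in ("total", "spliced_B6", "spliced_Cast"))
        and len({shapes.get(n) for n in ("total", "spliced_B6", "spliced_Cast")}) == 1
    ):
        excess = (
            dataset.layers["spliced_B6"] + dataset.layers["spliced_Cast"] - dataset.layers["total"]
        ).tocsr()
        if excess.nnz and excess.data.max() > 0:
            g, c = _first_offender(excess, lambda d: d > 0)
            gid = dataset.genes["gene_id"].iloc[g] if g < dataset.n_genes else g
            cid = dataset.cells["cell_id"].iloc[c] if c < dataset.n_cells else c
            violations.append(
                f"spliced_B6 + spliced_Cast exceeds total for gene {gid}, cell {cid}"
            )
    if "chromosome" in dataset.genes.columns:
        missing = dataset.genes["chromosome"].isna() | (
            dataset.genes["chromosome"].astype(str).str.len() == 0
        )
        for gid in dataset.genes.loc[missing, "gene_id"] if "gene_id" in dataset.genes else []:
            violations.append(f"gene {gid} has no chromosome label")
    return violations


def _first_offender(mat: sp.spmatrix, predicate):
    coo = mat.tocoo()
    offending = np.flatnonzero(predicate(coo.data))
    i = int(offending[0])
    return int(coo.row[i]), int(coo.col[i])


def deletion_length_kb(start: int, end: int) -> int:
    """Length of a deletion interval in kb, under the end - start convention.

    Genomic intervals in this package are stored 1-based inclusive, but
    reported lengths follow the common end - start rounding convention used
    for engineered deletions (e.g. a 773 kb Xic deletion).
    """
    return int(round((end - start) / 1000.0))
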