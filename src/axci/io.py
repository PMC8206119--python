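"""On-disk exchange format: Matrix Market layers plus TSV annotation tables.

A dataset directory contains one ``<layer>.mtx`` coordinate-format integer
matrix per layer, a ``genes.tsv`` and a ``cells.tsv``.  Writes are
deterministic (genes sorted by id, cells by cell id, canonical sparse
ordering) so that two writes of the same dataset are byte-identical.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import LAYER_NAMES, AllelicCountSet


class DataFormatError(ValueError):
    """Raised when an on-disk dataset violates the exchange-format contract."""


def write_allelic_counts(dataset: AllelicCountSet, directory_path) -> None:
    """Write ``dataset`` to ``directory_path`` in the exchange format."""
    path = Path(directory_path)
    path.mkdir(parents=True, exist_ok=True)
    order_g = np.argsort(dataset.genes["gene_id"].to_numpy(), kind="stable")
    order_c = np.argsort(dataset.cells["cell_id"].to_numpy(), kind="stable")
    ds = dataset.subset(order_g, order_c) if (
        not np.array_equal(order_g, np.arange(dataset.n_genes))
        or not np.array_equal(order_c, np.arange(dataset.n_cells))
    ) else dataset
    ds.genes.to_csv(path / "genes.tsv", sep="\t", index=False)
    ds.cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    for name in LAYER_NAMES:
        mat = sp.coo_matrix(ds.layers[name]).astype(np.int64)
        # mmwrite via an explicit buffer for stable line endings across platforms
        buf = _io.BytesIO()
        scipy.io.mmwrite(buf, mat, field="integer")
        (path / f"{name}.mtx").write_bytes(buf.getvalue())


def read_allelic_counts(directory_path) -> AllelicCountSet:
    """Read a dataset directory written by :func:`write_allelic_counts`.

    Raises
    ------
    DataFormatError
        If a layer file is missing, matrix dimensions do not match the
        annotation tables, or a layer contains negative or non-integer
        entries.
    """
    path = Path(directory_path)
    genes_file, cells_file = path / "genes.tsv", path / "cells.tsv"
    for f in (genes_file, cells_file):
        if not f.exists():
            raise DataFormatError(f"missing annotation file: {f}")
    genes = pd.read_csv(genes_file, sep="\t")
    cells = pd.read_csv(cells_file, sep="\t")
    layers = {}
    for name in LAYER_NAMES:
        f = path / f"{name}.mtx"
        if not f.exists():
            raise DataFormatError(f"missing layer file: {f}")
        mat = scipy.io.mmread(f)
        if mat.shape != (len(genes), len(cells)):
            raise DataFormatError(
                f"layer {name} has shape {mat.shape} but annotation tables imply "
                f"({len(genes)}, {len(cells)})"
            )
        data = sp.coo_matrix(mat).data
        if data.size and data.min() < 0:
            raise DataFormatError(f"layer {name} contains negative counts")
        if data.size and np.any(data != np.round(data)):
            raise DataFormatError(f"layer {name} contains non-integer entries")
        layers[name] = sp.csr_matrix(mat, dtype=np.int64)
    return AllelicCountSet(genes, cells, layers)
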