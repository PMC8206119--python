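"""Cell- and gene-level quality filters.

Cell filtering removes metric outliers (3x median-absolute-deviation windows
around the median) and then cells that appear to have lost one X chromosome
(XO cells: Xist undetected and >80% of allele-assignable X-linked reads from
a single allele).  Gene filtering removes genes detected in fewer than 20%
of cells and genes with >90% of allele-assignable reads on one allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import AllelicCountSet


@dataclass
class FilterStep:
    name: str
    threshold: object
    removed_ids: list
    n_retained: int


@dataclass
class QCReport:
    steps: list = field(default_factory=list)

    def add(self, name, threshold, removed_ids, n_retained):
        self.steps.append(FilterStep(name, threshold, list(removed_ids), n_retained))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, str(s.threshold), len(s.removed_ids), s.n_retained) for s in self.steps],
            columns=["filter", "threshold", "n_removed", "n_retained"],
        )

    def removed(self, name: str) -> list:
        for s in self.steps:
            if s.name == name:
                return s.removed_ids
        raise KeyError(name)


def mad_flags(values, k: float = 3.0, side: str = "both") -> np.ndarray:
    """Flag values outside ``median(x) +/- k * median(|x - median(x)|)``.

    The MAD is the raw (unscaled) median absolute deviation.  When all
    values are identical the MAD is zero and the window collapses onto the
    median, so only values different from the median are flagged.

    Parameters
    ----------
    side
        ``"high"`` flags values above the window, ``"low"`` below,
        ``"both"`` either side.
    """
    x = np.asarray(values, float)
    if not np.isfinite(x).any():
        raise ValueError("mad_flags requires at least one finite value")
    if k <= 0:
        raise ValueError("k must be positive")
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    hi = x > med + k * mad
    lo = x < med - k * mad
    if side == "high":
        flags = hi
    elif side == "low":
        flags = lo
    elif side == "both":
        flags = hi | lo
    else:
        raise ValueError(f"unknown side: {side!r}")
    return np.where(np.isfinite(x), flags, False)


def compute_xo_ratios(dataset: AllelicCountSet) -> np.ndarray:
    """Per-cell B6 fraction of allele-assignable X-linked spliced reads.

    ``R_c = sum_g e_B6 / sum_g (e_B6 + e_Cast)`` over X-linked genes
    excluding Xist; NaN where no allele-assignable X reads are present.
    """
    xmask = dataset.x_gene_mask(exclude_xist=True)
    b6 = np.asarray(dataset.layers["spliced_B6"][xmask].sum(axis=0)).ravel()
    cast = np.asarray(dataset.layers["spliced_Cast"][xmask].sum(axis=0)).ravel()
    denom = b6 + cast
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, b6 / np.maximum(denom, 1), np.nan)
    return r


#: Default metric -> flagged side for the MAD filters.
DEFAULT_METRIC_SIDES = {
    "n_reads": "low",
    "n_umi": "low",
    "n_genes": "low",
    "pct_mito": "high",
    "pct_ercc": "high",
    "dead_stain_intensity": "high",
}


def filter_cells(dataset: AllelicCountSet, mad_k: float = 3.0,
                 metric_sides: dict = None, xo_bounds=(0.2, 0.8),
                 xist_negative_max: int = 0, exclude_cells=None):
    """Apply the cell filters; returns ``(filtered dataset, QCReport)``.

    Order of operations: optional user exclusion list, per-metric MAD
    filters, then the XO rule (Xist-negative cells with ``R_c`` at or
    outside ``xo_bounds``).  Cells without allele-assignable X reads cannot
    be assessed for XO and are retained.
    """
    report = QCReport()
    keep = np.ones(dataset.n_cells, bool)
    ids = dataset.cells["cell_id"].to_numpy()

    if exclude_cells:
        drop = np.isin(ids, list(exclude_cells))
        keep &= ~drop
        report.add("manual_exclusion", None, ids[drop], int(keep.sum()))

    metric_sides = DEFAULT_METRIC_SIDES if metric_sides is None else metric_sides
    for metric, side in metric_sides.items():
        if metric not in dataset.cells.columns:
            continue
        flags = mad_flags(dataset.cells[metric].to_numpy(float), k=mad_k, side=side)
        removed = ids[keep & flags]
        keep &= ~flags
        report.add(f"mad_{metric}", f"{mad_k}x MAD {side}", removed, int(keep.sum()))

    r = compute_xo_ratios(dataset)
    xist = dataset.xist_counts("total")
    lo, hi = xo_bounds
    xo = (xist <= xist_negative_max) & np.isfinite(r) & ((r >= hi) | (r <= lo))
    removed = ids[keep & xo]
    keep &= ~xo
    report.add("xo_cells", f"Xist<= {xist_negative_max} and R<= {lo} or >= {hi}",
               removed, int(keep.sum()))

    out = dataset.subset(cell_mask=keep)
    out.cells = out.cells.assign(xo_ratio=r[keep])
    return out, report


def filter_genes(dataset: AllelicCountSet, detect_frac: float = 0.2,
                 allelic_skew: float = 0.9, skew_filter_scope: str = "both"):
    """Apply the gene filters; returns ``(filtered dataset, QCReport)``.

    Two gene sets are tracked, mirroring the separate allele-specific (AS)
    and non-allelic analyses:

    * the non-allelic set requires detection (total count > 0) in at least
      ``detect_frac`` of cells;
    * the AS set requires detection of allele-assignable counts in at least
      ``detect_frac`` of cells and no extreme allelic skew (more than
      ``allelic_skew`` of summed AS counts on one allele).

    With ``skew_filter_scope="both"`` (default) the skew filter also removes
    genes from the non-allelic set; ``"as_only"`` restricts it to the AS
    set.  The returned dataset is restricted to the union of the two sets
    and carries ``in_total_set`` / ``in_as_set`` gene columns.
    """
    report = QCReport()
    ids = dataset.genes["gene_id"].to_numpy()
    total = dataset.dense("total")
    b6 = dataset.dense("spliced_B6")
    cast = dataset.dense("spliced_Cast")

    det_total = (total > 0).mean(axis=1) >= detect_frac
    det_as = ((b6 + cast) > 0).mean(axis=1) >= detect_frac
    report.add("detection_total", f">= {detect_frac:.0%} of cells",
               ids[~det_total], int(det_total.sum()))

    sum_b6, sum_cast = b6.sum(axis=1), cast.sum(axis=1)
    tot_as = sum_b6 + sum_cast
    with np.errstate(invalid="ignore", divide="ignore"):
        major = np.where(tot_as > 0,
                         np.maximum(sum_b6, sum_cast) / np.maximum(tot_as, 1), 0.0)
    skew_ok = major <= allelic_skew  # the rule is strictly >90%
    report.add("allelic_skew", f"> {allelic_skew:.0%} on one allele",
               ids[~skew_ok], int(skew_ok.sum()))

    in_as = det_as & skew_ok
    in_total = det_total & (skew_ok if skew_filter_scope == "both" else True)
    union = in_as | in_total
    out = dataset.subset(gene_mask=union)
    out.genes = out.genes.assign(in_total_set=in_total[union], in_as_set=in_as[union])
    report.add("retained_union", None, ids[~union], int(union.sum()))
    return out, report
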