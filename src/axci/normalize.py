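"""Cell-level CPM normalization and the bootstrapped X:A expression ratio.

Counts are scaled to counts-per-million with cell-specific scaling factors
``f_c`` derived from the autosomal non-allelic count matrix:

``CPM_gc = 1e6 * e_gc / (f_c * sum_g' e_g'c)``

where the denominator runs over autosomal genes.  Allelic layers are
normalized with the same factors and denominators.  The composition factors
``f_c`` default to a median-ratio estimator computed within each time point
(each cell against the pooled pseudo-cell of its time point); TMM factors
are available for bulk tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import AllelicCountSet


@dataclass
class NormalizedMatrix:
    """CPM layers (dense genes x cells float arrays) plus the factors used."""

    layers: dict
    scaling_factors: np.ndarray
    denominators: np.ndarray  #: per-cell autosomal total counts

    def layer(self, name):
        return self.layers[name]


def _median_ratio_factors(counts: np.ndarray) -> np.ndarray:
    """Composition factors of one cell group against its pooled pseudo-cell.

    Works on proportions, so pure depth differences yield factors of 1.
    """
    colsum = counts.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("zero-count cell encountered; remove it during QC")
    props = counts / colsum
    ref = counts.sum(axis=1) / counts.sum()
    factors = np.ones(counts.shape[1])
    for c in range(counts.shape[1]):
        mask = (props[:, c] > 0) & (ref > 0)
        if mask.any():
            factors[c] = np.median(props[mask, c] / ref[mask])
    return factors


def tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors for bulk count tables.

    The reference sample is the library whose upper quartile of scaled
    counts is closest to the mean upper quartile.  M values (log2 fold
    changes against the reference) are trimmed by ``trim_m`` on each side
    and A values (average log2 abundance) by ``trim_a``; the factor is the
    2-power of the mean of the surviving M values, renormalized to unit
    geometric mean.
    """
    counts = np.asarray(counts, float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero-count sample")
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if not ok.any():
            continue
        pj, pr = counts[ok, j] / lib[j], counts[ok, ref] / lib[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        keep = np.ones(m.size, bool)
        for vals, trim in ((m, trim_m), (a, trim_a)):
            lo, hi = np.quantile(vals, [trim, 1 - trim])
            keep &= (vals >= lo) & (vals <= hi)
        factors[j] = 2.0 ** m[keep].mean() if keep.any() else 1.0
    return factors / np.exp(np.mean(np.log(factors)))


def compute_scaling_factors(dataset: AllelicCountSet, method: str = "median_ratio",
                            groupby: str = "time_point_days") -> np.ndarray:
    """Per-cell composition factors from the autosomal total count matrix.

    ``method`` is one of ``"unit"``, ``"median_ratio"`` (within ``groupby``
    groups) or ``"tmm"``.  Factors are renormalized to unit geometric mean
    across all cells.
    """
    auto = dataset.autosomal_gene_mask()
    counts = dataset.dense("total")[auto].astype(float)
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("zero-count cell encountered; remove it during QC")
    if method == "unit":
        return np.ones(dataset.n_cells)
    if method == "tmm":
        factors = tmm_factors(counts)
    elif method == "median_ratio":
        factors = np.ones(dataset.n_cells)
        groups = dataset.cells[groupby] if groupby in dataset.cells.columns else None
        if groups is None:
            factors = _median_ratio_factors(counts)
        else:
            for _, idx in dataset.cells.groupby(groups).indices.items():
                factors[idx] = _median_ratio_factors(counts[:, idx])
    else:
        raise ValueError(f"unknown method: {method!r}")
    return factors / np.exp(np.mean(np.log(factors)))


def cpm_normalize(dataset: AllelicCountSet, scaling_factors=None) -> NormalizedMatrix:
    """CPM-normalize every layer with shared factors and autosomal denominators."""
    f = np.ones(dataset.n_cells) if scaling_factors is None else np.asarray(scaling_factors, float)
    if np.any(f <= 0):
        raise ValueError("scaling factors must be positive")
    auto = dataset.autosomal_gene_mask()
    denom = np.asarray(dataset.layers["total"][auto].sum(axis=0)).ravel().astype(float)
    if np.any(denom == 0):
        raise ValueError("zero autosomal counts in at least one cell; remove during QC")
    scale = 1e6 / (f * denom)
    layers = {name: dataset.dense(name) * scale[None, :] for name in dataset.layers}
    return NormalizedMatrix(layers=layers, scaling_factors=f, denominators=denom)


def xa_ratio_bootstrap(norm: NormalizedMatrix, x_mask, autosome_mask,
                       n_boot: int = 1000, rng=None, layer: str = "total",
                       numerator=None) -> np.ndarray:
    """Bootstrapped per-cell X-to-autosome expression ratio.

    For each bootstrap draw, a set of autosomal genes of the same size as
    the X-linked set is resampled with replacement and the ratio of mean
    X-linked CPM to mean resampled autosomal CPM is computed; the returned
    per-cell estimate is the median across ``n_boot`` draws.  The same
    resampled gene sets are shared across cells (the estimator is unchanged;
    only across-cell correlation of the bootstrap noise is introduced).

    ``numerator`` optionally overrides the X-linked CPM matrix (e.g. a
    single allele's layer restricted to the same genes).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    x_mask = np.asarray(x_mask, bool)
    autosome_mask = np.asarray(autosome_mask, bool)
    if x_mask.sum() == 0:
        raise ValueError("empty X-linked gene set")
    cpm = norm.layer(layer)
    x_mean = (cpm[x_mask].mean(axis=0) if numerator is None
              else np.asarray(numerator).mean(axis=0))
    auto = norm.layer("total")[autosome_mask]
    n_x, n_auto = int(x_mask.sum()), auto.shape[0]
    ratios = np.empty((n_boot, cpm.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n_auto, size=n_x)
        denom = auto[idx].mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios[b] = np.where(denom > 0, x_mean / denom, np.nan)
    return np.nanmedian(ratios, axis=0)


def xa_ratio_by_class(norm: NormalizedMatrix, dataset: AllelicCountSet,
                      level_class, allele_mode: str = "total", xi_allele=None,
                      n_boot: int = 1000, rng=None) -> pd.DataFrame:
    """Per-cell X:A ratios labelled by Xist level class and day.

    ``allele_mode="Xi"``/``"Xa"`` restricts the X-linked numerator to the
    CPM of the cell's inactive/active allele (cells without a defined Xi are
    dropped); ``"total"`` uses the non-allelic layer.
    """
    x_mask = dataset.x_gene_mask(exclude_xist=True)
    auto_mask = dataset.autosomal_gene_mask()
    if allele_mode == "total":
        ratios = xa_ratio_bootstrap(norm, x_mask, auto_mask, n_boot=n_boot, rng=rng)
        keep = np.ones(dataset.n_cells, bool)
    elif allele_mode in ("Xi", "Xa"):
        if xi_allele is None:
            raise ValueError("allele_mode Xi/Xa requires per-cell xi_allele labels")
        xi = np.asarray(xi_allele, object)
        keep = np.isin(xi, ["B6", "Cast"])
        num = np.empty((int(x_mask.sum()), dataset.n_cells))
        for allele in ("B6", "Cast"):
            target = allele if allele_mode == "Xi" else ("Cast" if allele == "B6" else "B6")
            cols = xi == allele
            num[:, cols] = norm.layer(f"spliced_{target}")[x_mask][:, cols]
        ratios = xa_ratio_bootstrap(norm, x_mask, auto_mask, n_boot=n_boot, rng=rng,
                                    numerator=num)
    else:
        raise ValueError(f"unknown allele_mode: {allele_mode!r}")
    out = pd.DataFrame({
        "cell_id": dataset.cells["cell_id"],
        "time_point_days": dataset.cells["time_point_days"],
        "level_class": np.asarray(level_class, object),
        "xa_ratio": ratios,
    })
    return out[keep].reset_index(drop=True)
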