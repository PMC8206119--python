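"""Gene-relative RNA velocity, the early-silencing statistic dX, and the
allelic-fraction PCA projection.

A simplified gene-relative velocity model: spliced (s) and unspliced (u)
expression are pooled over each cell's k nearest neighbours; the
steady-state slope ``gamma`` of each gene is fitted through the origin on
the cells in the extreme (top and bottom ``fit_quantile``) pooled-spliced
quantiles; velocity is ``u - gamma * s`` and the predicted future state is
``P = max(0, s + v)`` with a unit extrapolation step.  The per-cell
early-silencing statistic is ``dX_c = sum_g M_gc / sum_g P_gc`` over fitted
X-linked genes: values above 1 indicate that X-linked expression is
predicted to fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


@dataclass
class VelocityFit:
    gamma: np.ndarray  #: per-gene steady-state slope (NaN where unfitted)
    fitted: np.ndarray  #: boolean per-gene fit mask
    M: np.ndarray  #: measured (pooled spliced) expression, genes x cells
    P: np.ndarray  #: predicted future expression, genes x cells
    neighbors: np.ndarray  #: cells x k neighbour indices used for pooling
    k_cells: int
    fit_quantile: float


def knn_pooling_indices(spliced: np.ndarray, k_cells: int = 20, n_pcs: int = 30,
                        random_state: int = 0) -> np.ndarray:
    """Neighbour indices (including the cell itself) for count pooling.

    Euclidean k-nearest neighbours in the top principal components of
    log1p-transformed spliced expression.
    """
    x = np.log1p(np.asarray(spliced, float)).T  # cells x genes
    n_cells = x.shape[0]
    k = min(k_cells, n_cells)
    n_comp = min(n_pcs, n_cells - 1, x.shape[1])
    if n_comp >= 2 and n_cells > 2:
        x = PCA(n_components=n_comp, random_state=random_state).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    return nn.kneighbors(x, return_distance=False)


def _pool(mat: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    return mat[:, neighbors].sum(axis=2)


def fit_gene_velocity(spliced, unspliced, k_cells: int = 20, fit_quantile: float = 0.025,
                      min_spliced_mean: float = 1.0, min_unspliced_mean: float = 0.5,
                      raw_spliced=None, raw_unspliced=None, n_pcs: int = 30,
                      neighbors=None) -> VelocityFit:
    """Fit the gene-relative velocity model on genes x cells matrices.

    Genes whose mean raw spliced expression is <= ``min_spliced_mean`` or
    mean raw unspliced expression is <= ``min_unspliced_mean`` are marked
    unfitted (the floors are evaluated on ``raw_spliced``/``raw_unspliced``
    when given, else on the inputs).  ``gamma`` is the through-origin slope
    fitted on the cells in the top and bottom ``fit_quantile`` of each
    gene's pooled spliced expression; degenerate fits (``gamma <= 0``) mark
    the gene unfitted.
    """
    s = np.asarray(spliced, float)
    u = np.asarray(unspliced, float)
    if s.shape != u.shape:
        raise ValueError("spliced and unspliced matrices must share a shape")
    floor_s = np.asarray(raw_spliced, float) if raw_spliced is not None else s
    floor_u = np.asarray(raw_unspliced, float) if raw_unspliced is not None else u
    passes = (floor_s.mean(axis=1) > min_spliced_mean) & (
        floor_u.mean(axis=1) > min_unspliced_mean)

    if neighbors is None:
        neighbors = knn_pooling_indices(s, k_cells=k_cells, n_pcs=n_pcs)
    sp_, up_ = _pool(s, neighbors), _pool(u, neighbors)

    n_genes, n_cells = s.shape
    gamma = np.full(n_genes, np.nan)
    q = fit_quantile
    for g in np.flatnonzero(passes):
        sg, ug = sp_[g], up_[g]
        lo, hi = np.quantile(sg, [q, 1 - q])
        extreme = (sg <= lo) | (sg >= hi)
        denom = float(np.sum(sg[extreme] ** 2))
        if denom <= 0:
            continue
        gamma[g] = float(np.sum(sg[extreme] * ug[extreme]) / denom)
    fitted = passes & np.isfinite(gamma) & (gamma > 0)
    gamma[~fitted] = np.nan

    velocity = up_ - gamma[:, None] * sp_
    P = np.clip(sp_ + velocity, 0.0, None)
    P[~fitted] = np.nan
    return VelocityFit(gamma=gamma, fitted=fitted, M=sp_, P=P, neighbors=neighbors,
                       k_cells=k_cells, fit_quantile=fit_quantile)


def compute_deltax(fit: VelocityFit, x_mask) -> np.ndarray:
    """Per-cell dX = sum(M) / sum(P) over fitted X-linked genes."""
    use = np.asarray(x_mask, bool) & fit.fitted
    if not use.any():
        raise ValueError("no fitted X-linked genes available for dX")
    m = fit.M[use].sum(axis=0)
    p = fit.P[use].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(p > 0, m / p, np.nan)


def allelic_fraction_matrix(spliced_b6, spliced_cast) -> np.ndarray:
    """B6 fraction ``l = b6 / (b6 + cast)`` per gene/cell; NaN where both 0."""
    b6 = np.asarray(spliced_b6, float)
    cast = np.asarray(spliced_cast, float)
    denom = b6 + cast
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, b6 / np.where(denom > 0, denom, 1.0), np.nan)


def _fix_signs(pca: PCA) -> PCA:
    # reproducible orientation: the largest-magnitude loading is positive
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[i] = -comp
    return pca


def project_velocity_pca(l_measured: np.ndarray, l_predicted: np.ndarray,
                         n_components: int = 2):
    """PCA of the measured B6-fraction matrix plus predicted displacements.

    ``l_measured``/``l_predicted`` are X-genes x cells B6-fraction matrices;
    NaN entries are imputed to 0.5 (no allelic information).  Returns
    ``(embedding, displacement, pca)`` where ``displacement`` is the
    projection of the predicted fractions minus the embedding.
    """
    lm = np.nan_to_num(np.asarray(l_measured, float), nan=0.5).T  # cells x genes
    lp = np.nan_to_num(np.asarray(l_predicted, float), nan=0.5).T
    pca = PCA(n_components=min(n_components, lm.shape[0] - 1, lm.shape[1]))
    emb = pca.fit(lm)
    _fix_signs(pca)
    embedding = pca.transform(lm)
    displacement = pca.transform(lp) - embedding
    return embedding, displacement, pca


def velocity_from_dataset(dataset, norm, k_cells: int = 20, fit_quantile: float = 0.025,
                          min_spliced_mean: float = 1.0, min_unspliced_mean: float = 0.5):
    """End-to-end velocity analysis of an :class:`AllelicCountSet`.

    The container carries unspliced counts only for allele-assignable
    molecules, so the total-scale unspliced signal of each gene is estimated
    by inverse thinning: the summed allelic unspliced counts divided by the
    gene's allele-assignable rate (summed allelic over total spliced counts
    across cells).  The velocity model is fitted on total spliced CPM vs the
    rescaled unspliced CPM (expression floors evaluated on the corresponding
    raw counts), per-cell dX is computed over fitted X-linked genes, and
    measured/predicted allelic B6-fraction matrices feed the PCA projection.
    """
    raw_s = dataset.dense("total").astype(float)
    raw_u_as = (dataset.dense("unspliced_B6") + dataset.dense("unspliced_Cast")).astype(float)
    as_spliced = (dataset.dense("spliced_B6") + dataset.dense("spliced_Cast")).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        as_rate = as_spliced.sum(axis=1) / np.maximum(raw_s.sum(axis=1), 1.0)
    scale = np.where(as_rate > 0, 1.0 / np.maximum(as_rate, 1e-12), 0.0)[:, None]
    raw_u = raw_u_as * scale
    s = norm.layer("total")
    u = (norm.layer("unspliced_B6") + norm.layer("unspliced_Cast")) * scale
    fit = fit_gene_velocity(s, u, k_cells=k_cells, fit_quantile=fit_quantile,
                            min_spliced_mean=min_spliced_mean,
                            min_unspliced_mean=min_unspliced_mean,
                            raw_spliced=raw_s, raw_unspliced=raw_u)
    x_mask = dataset.x_gene_mask(exclude_xist=True)
    deltax = compute_deltax(fit, x_mask)

    # per-cell (unpooled) allelic fractions keep cells silencing opposite
    # alleles from blending through shared neighbourhoods
    use = x_mask & fit.fitted
    sb6 = norm.layer("spliced_B6")[use]
    sca = norm.layer("spliced_Cast")[use]
    ub6 = norm.layer("unspliced_B6")[use]
    uca = norm.layer("unspliced_Cast")[use]
    gam = fit.gamma[use][:, None]
    pb6 = np.clip(sb6 + (ub6 - gam * sb6), 0.0, None)
    pca_ = np.clip(sca + (uca - gam * sca), 0.0, None)
    l_meas = allelic_fraction_matrix(sb6, sca)
    l_pred = allelic_fraction_matrix(pb6, pca_)
    embedding, displacement, pca = project_velocity_pca(l_meas, l_pred)
    return fit, deltax, embedding, displacement
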