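"""Gene- and allele-specific silencing dynamics along XCI progress.

The per-cell XCI progress of monoallelically Xist-expressing cells,

``XP_c = 100 * (1 - (sum_g e_Xi + 0.01) / (sum_g e_Xa + 0.01))``

(X-linked genes except Xist, allele-assignable spliced counts, negative
values clamped to 0), orders cells by how much of the inactive X has been
silenced.  Cells past XP = 10 are grouped into ten equal-width XP bins per
Xi allele; per gene and bin a pooled Xi:Xa count ratio is formed, corrected
for basal allelic skew measured in day-0 Xist-negative cells, and a
no-intercept log-linear fit ``log2(r*) = -beta * XP`` yields the relative
silencing rate and the half-time ``XP50 = 1/beta`` (capped at 100).  A
joint two-allele fit with an allele-interaction slope and an ANOVA F test
flags differentially silenced genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import AllelicCountSet
from .qc import compute_xo_ratios
from .screen import bh_adjust

PSEUDOCOUNT = 0.01
CATEGORY_NAMES = ("fast", "intermediate", "slow", "escape")


def xp_from_sums(sum_xi, sum_xa) -> np.ndarray:
    """XP value(s) from summed Xi and Xa counts, clamped at 0."""
    xp = 100.0 * (1.0 - (np.asarray(sum_xi, float) + PSEUDOCOUNT)
                  / (np.asarray(sum_xa, float) + PSEUDOCOUNT))
    return np.clip(xp, 0.0, None)


def compute_xp(dataset: AllelicCountSet, xi_allele) -> np.ndarray:
    """Per-cell XCI progress for cells with a defined Xi allele.

    ``xi_allele`` holds "B6"/"Cast" per cell (anything else yields NaN:
    biallelic and Xist-negative cells have no defined Xi/Xa axis).
    """
    xmask = dataset.x_gene_mask(exclude_xist=True)
    b6 = np.asarray(dataset.layers["spliced_B6"][xmask].sum(axis=0)).ravel()
    cast = np.asarray(dataset.layers["spliced_Cast"][xmask].sum(axis=0)).ravel()
    xi = np.asarray(xi_allele, object)
    xp = np.full(dataset.n_cells, np.nan)
    m = xi == "B6"
    xp[m] = xp_from_sums(b6[m], cast[m])
    m = xi == "Cast"
    xp[m] = xp_from_sums(cast[m], b6[m])
    return xp


@dataclass
class BinAssignment:
    bin_index: np.ndarray  #: per input cell; -1 for excluded cells
    edges: np.ndarray  #: bin edges, length n_bins + 1
    xp_b: np.ndarray = None  #: pooled per-bin XP (set by :func:`bin_xp`)


def bin_cells(xp_values, n_bins: int = 10, min_xp: float = 10.0) -> BinAssignment:
    """Equal-width XP bins over the retained cells (XP > ``min_xp``).

    Bins are left-closed/right-open; the maximum falls in the last bin.
    """
    xp = np.asarray(xp_values, float)
    retained = np.isfinite(xp) & (xp > min_xp)
    idx = np.full(xp.size, -1, int)
    if not retained.any():
        return BinAssignment(idx, np.array([]))
    lo, hi = xp[retained].min(), xp[retained].max()
    if hi == lo:
        edges = np.array([lo, lo])
        idx[retained] = 0
        return BinAssignment(idx, edges)
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, xp[retained], side="right") - 1, 0, n_bins - 1)
    idx[retained] = which
    return BinAssignment(idx, edges)


def bin_xp(bins: BinAssignment, xi_counts, xa_counts) -> np.ndarray:
    """Pooled XP per bin from the cells' summed Xi and Xa counts."""
    n_bins = max(len(bins.edges) - 1, 1)
    xi = np.asarray(xi_counts, float)
    xa = np.asarray(xa_counts, float)
    xp_b = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = bins.bin_index == b
        if m.any():
            xp_b[b] = float(xp_from_sums(xi[m].sum(), xa[m].sum()))
    bins.xp_b = xp_b
    return xp_b


def bin_gene_ratio(gene_xi_counts, gene_xa_counts, bins: BinAssignment,
                   min_cells: int = 5, min_as_counts: int = 25,
                   min_bins: int = 5):
    """Per-bin pooled Xi:Xa ratio for one gene, with eligibility filters.

    Bins with fewer than ``min_cells`` cells or fewer than ``min_as_counts``
    allele-assignable counts of this gene are dropped; the gene is eligible
    only with at least ``min_bins`` surviving bins.  Returns a frame with
    one row per surviving bin plus an ``eligible`` flag.
    """
    xi = np.asarray(gene_xi_counts, float)
    xa = np.asarray(gene_xa_counts, float)
    n_bins = max(len(bins.edges) - 1, 1)
    rows = []
    for b in range(n_bins):
        m = bins.bin_index == b
        n_cells = int(m.sum())
        if n_cells == 0:
            continue
        s_xi, s_xa = xi[m].sum(), xa[m].sum()
        as_counts = s_xi + s_xa
        if n_cells < min_cells or as_counts < min_as_counts:
            continue
        r = (s_xi + PSEUDOCOUNT) / (s_xa + PSEUDOCOUNT)
        xp_b = bins.xp_b[b] if bins.xp_b is not None else np.nan
        rows.append((b, xp_b, r, n_cells, as_counts))
    table = pd.DataFrame(rows, columns=["bin", "xp_b", "r", "n_cells", "as_counts"])
    return table, len(table) >= min_bins


def basal_skew(dataset: AllelicCountSet, level_class, xo_ratios=None,
               r_bounds=(0.4, 0.6)) -> np.ndarray:
    """Per-gene basal B6:Cast skew from balanced day-0 Xist-negative cells.

    ``s_g = (sum e_B6 + 0.01) / (sum e_Cast + 0.01)`` over day-0
    Xist-negative cells with an X-chromosomal ratio within ``r_bounds``.
    """
    r = compute_xo_ratios(dataset) if xo_ratios is None else np.asarray(xo_ratios, float)
    day0 = dataset.cells["time_point_days"].to_numpy() == 0
    neg = np.asarray(level_class, object) == "negative"
    balanced = np.isfinite(r) & (r >= r_bounds[0]) & (r <= r_bounds[1])
    cells = day0 & neg & balanced
    if not cells.any():
        raise ValueError(
            "no day-0 Xist-negative cells with balanced allelic X ratio; basal "
            "skew cannot be estimated (check QC filters and day-0 sampling)")
    b6 = np.asarray(dataset.layers["spliced_B6"][:, cells].sum(axis=1)).ravel()
    cast = np.asarray(dataset.layers["spliced_Cast"][:, cells].sum(axis=1)).ravel()
    return (b6 + PSEUDOCOUNT) / (cast + PSEUDOCOUNT)


def normalize_ratio(r, s_g: float, xi_allele: str):
    """Basal-skew-corrected ratio ``r* = r / r_g0`` (``r_g0`` = s for Xi=B6,
    1/s for Xi=Cast)."""
    r0 = s_g if xi_allele == "B6" else 1.0 / s_g
    return np.asarray(r, float) / r0


def fit_xp50(xp_bins, log2_rstar_bins):
    """No-intercept least-squares fit of ``log2(r*) = -beta * XP``.

    Returns ``(beta, xp50)`` with ``xp50 = 1/beta`` capped at 100;
    non-positive beta yields the escape-like cap of 100.
    """
    xp = np.asarray(xp_bins, float)
    y = np.asarray(log2_rstar_bins, float)
    denom = float((xp ** 2).sum())
    if denom == 0:
        return 0.0, 100.0
    beta = -float((xp * y).sum()) / denom
    xp50 = 1.0 / beta if beta > 0 else np.inf
    return beta, float(min(xp50, 100.0))


def categorize_xp50(xp50_values, k: int = 4, seed: int = 0):
    """Order genes into fast/intermediate/slow/escape by 1-D K-means.

    Clusters are ordered by ascending centroid and mapped onto the four
    category names.  Degenerate inputs (fewer distinct values than ``k``)
    fall back to fewer clusters; if everything sits at the cap of 100 all
    genes are labelled escape.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(xp50_values, float)
    ok = np.isfinite(x)
    labels = np.full(x.shape, "", dtype=object)
    vals = x[ok]
    if vals.size == 0:
        return labels
    uniq = np.unique(vals)
    if uniq.size == 1:
        labels[ok] = "escape" if uniq[0] >= 100.0 else "intermediate"
        return labels
    k_eff = min(k, uniq.size)
    km = KMeans(n_clusters=k_eff, n_init=50, random_state=seed).fit(vals.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    rank_of = {orig: r for r, orig in enumerate(order)}
    if k_eff == k:
        name_of = dict(enumerate(CATEGORY_NAMES))
    else:
        # spread the available ranks over the canonical names, keeping the
        # top cluster "escape" when it sits at the cap
        centers = km.cluster_centers_.ravel()[order]
        name_of = {}
        for r, c in enumerate(centers):
            if c >= 99.0:
                name_of[r] = "escape"
            else:
                name_of[r] = CATEGORY_NAMES[min(r, k - 2)]
    lab = np.array([name_of[rank_of[l]] for l in km.labels_], dtype=object)
    labels[ok] = lab
    return labels


def differential_silencing(xp_b6, log2_rstar_b6, xp_cast, log2_rstar_cast):
    """Joint no-intercept fit with an allele-interaction slope plus F test.

    Model: ``log2(r*) = beta1 * XP + beta2 * XP * a`` with ``a = 1`` for
    Xi = Cast.  Returns ``(beta1, beta2, F, p)`` testing H0: beta2 = 0
    (note the sign convention: the fitted slopes are the negated silencing
    rates; ``-beta1`` and ``-(beta1 + beta2)`` estimate the B6 and Cast
    rates).
    """
    xp = np.concatenate([np.asarray(xp_b6, float), np.asarray(xp_cast, float)])
    y = np.concatenate([np.asarray(log2_rstar_b6, float),
                        np.asarray(log2_rstar_cast, float)])
    a = np.concatenate([np.zeros(len(np.atleast_1d(xp_b6))),
                        np.ones(len(np.atleast_1d(xp_cast)))])
    x_full = np.column_stack([xp, xp * a])
    x_null = xp.reshape(-1, 1)
    n = y.size
    rss_full = _rss(y, x_full)
    rss_null = _rss(y, x_null)
    df_resid = n - 2  # no-intercept model with two slopes
    if df_resid <= 0:
        return np.nan, np.nan, np.nan, np.nan
    beta_full, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    if rss_full <= 1e-300:
        f = 0.0 if rss_null - rss_full <= 1e-300 else np.inf
    else:
        f = (rss_null - rss_full) / (rss_full / df_resid)
    p = float(scipy.stats.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return float(beta_full[0]), float(beta_full[1]), float(f), p


def _rss(y, x):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------- driver
def fit_silencing_table(dataset: AllelicCountSet, classification: pd.DataFrame,
                        n_bins: int = 10, min_xp: float = 10.0, min_cells: int = 5,
                        min_as_counts: int = 25, min_bins: int = 5,
                        kmeans_seed: int = 0, alpha: float = 0.05):
    """End-to-end silencing-dynamics analysis.

    Returns ``(fits, differential)``: a per-gene x per-allele table of
    fitted rates, half-times and categories, and a per-gene differential
    silencing table (joint fit, F-test p, BH-adjusted p).
    """
    xmask = dataset.x_gene_mask(exclude_xist=True)
    xgenes = dataset.genes.loc[xmask, ["gene_id", "name"]].reset_index(drop=True)
    b6 = dataset.dense("spliced_B6")[xmask].astype(float)
    cast = dataset.dense("spliced_Cast")[xmask].astype(float)

    xi = classification["xi_allele"].to_numpy(object)
    xp = compute_xp(dataset, xi)
    skew = basal_skew(dataset, classification["level_class"].to_numpy(object))[xmask]

    per_allele = {}
    for allele, xi_counts, xa_counts in (("B6", b6, cast), ("Cast", cast, b6)):
        cells = xi == allele
        bins = bin_cells(np.where(cells, xp, np.nan), n_bins=n_bins, min_xp=min_xp)
        bin_xp(bins, xi_counts.sum(axis=0), xa_counts.sum(axis=0))
        rows = []
        for gi in range(len(xgenes)):
            table, eligible = bin_gene_ratio(xi_counts[gi], xa_counts[gi], bins,
                                             min_cells=min_cells,
                                             min_as_counts=min_as_counts,
                                             min_bins=min_bins)
            if not eligible:
                rows.append((gi, False, np.nan, np.nan, None))
                continue
            rstar = normalize_ratio(table["r"].to_numpy(), skew[gi], allele)
            beta, xp50 = fit_xp50(table["xp_b"].to_numpy(), np.log2(rstar))
            rows.append((gi, True, beta, xp50,
                         (table["xp_b"].to_numpy(), np.log2(rstar))))
        per_allele[allele] = rows

    fit_rows = []
    for allele, rows in per_allele.items():
        xp50s = np.array([r[3] for r in rows], float)
        cats = categorize_xp50(xp50s, seed=kmeans_seed)
        for (gi, eligible, beta, xp50, _), cat in zip(rows, cats):
            fit_rows.append((xgenes["gene_id"].iloc[gi], xgenes["name"].iloc[gi],
                             allele, eligible, beta, xp50, cat if eligible else ""))
    fits = pd.DataFrame(fit_rows, columns=["gene_id", "name", "xi_allele", "eligible",
                                           "beta", "xp50", "category"])

    diff_rows = []
    for gi in range(len(xgenes)):
        rb = per_allele["B6"][gi]
        rc = per_allele["Cast"][gi]
        if not (rb[1] and rc[1]):
            continue
        (xb, yb), (xc, yc) = rb[4], rc[4]
        b1, b2, fstat, p = differential_silencing(xb, yb, xc, yc)
        diff_rows.append((xgenes["gene_id"].iloc[gi], xgenes["name"].iloc[gi],
                          b1, b2, fstat, p))
    differential = pd.DataFrame(diff_rows, columns=["gene_id", "name", "beta1",
                                                    "beta2", "f_stat", "p_value"])
    if len(differential):
        differential["p_adj"] = bh_adjust(differential["p_value"].to_numpy())
        differential["differential"] = differential["p_adj"] <= alpha
    else:
        differential["p_adj"] = []
        differential["differential"] = []
    return fits, differential
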