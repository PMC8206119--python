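"""Putative Xist-regulator screens.

Cells are grouped into high/low expression groups (1-D K-means on Xist CPM
or on the early-silencing statistic dX), differential expression between
groups is tested with a two-part hurdle model (logistic detection part plus
Gaussian part on log2(CPM+1) among detected cells, chi-square likelihood
ratio test), and, independently, every gene is rank-correlated with the
grouping variable.  Results of the eight analyses (Xist/dX x day 1/2 x
DE/correlation) are integrated by support counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.cluster import KMeans


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (NaNs propagate)."""
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    n = q.size
    if n == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


@dataclass
class GroupAssignment:
    group: np.ndarray  #: per cell: "high" | "low" | "middle"
    cluster: np.ndarray  #: per cell cluster id, ordered by ascending centroid
    centroids: np.ndarray
    valid: bool  #: both groups reached ``min_cells``
    n_high: int
    n_low: int


def kmeans_group_cells(values, k: int, n_top: int = 1, n_bottom: int = 1,
                       min_cells: int = 50, seed: int = 0) -> GroupAssignment:
    """1-D K-means grouping of cells into high/low expression groups.

    Clusters are ranked by centroid (ties broken by size, larger first);
    the high group is the union of the top ``n_top`` clusters, the low
    group the union of the bottom ``n_bottom``.  The assignment is flagged
    invalid when either group has fewer than ``min_cells`` cells.
    """
    x = np.asarray(values, float).reshape(-1, 1)
    if np.unique(x).size < k:
        raise ValueError(f"K-means with K={k} requires at least {k} distinct values")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(x)
    centroids = km.cluster_centers_.ravel()
    sizes = np.bincount(km.labels_, minlength=k)
    order = sorted(range(k), key=lambda i: (centroids[i], -sizes[i]))
    rank_of = {orig: rank for rank, orig in enumerate(order)}
    ranks = np.array([rank_of[l] for l in km.labels_])
    group = np.full(x.shape[0], "middle", dtype=object)
    group[ranks >= k - n_top] = "high"
    group[ranks < n_bottom] = "low"
    n_high, n_low = int((group == "high").sum()), int((group == "low").sum())
    return GroupAssignment(group=group, cluster=ranks, centroids=centroids[order],
                           valid=(n_high >= min_cells and n_low >= min_cells),
                           n_high=n_high, n_low=n_low)


def _logistic_lr(z, g, cdr):
    """Likelihood-ratio contribution of the detection part (and its df)."""
    if z.min() == z.max():
        return 0.0, 0
    x_null = sm.add_constant(cdr, has_constant="add")
    x_full = np.column_stack([x_null, g])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_null = sm.GLM(z, x_null, family=sm.families.Binomial()).fit(maxiter=100)
            fit_full = sm.GLM(z, x_full, family=sm.families.Binomial()).fit(maxiter=100)
        lr = max(fit_null.deviance - fit_full.deviance, 0.0)
    except Exception:
        # perfect separation: the full-model deviance tends to 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_null = sm.GLM(z, x_null, family=sm.families.Binomial()).fit(maxiter=100)
        lr = max(fit_null.deviance, 0.0)
    return lr, 1


def _gaussian_lr(y, g, cdr):
    """Gaussian-MLE LR contribution of the continuous part among detected cells."""
    n = y.size
    if n < 4 or np.unique(g).size < 2:
        return 0.0, 0
    x_null = np.column_stack([np.ones(n), cdr])
    x_full = np.column_stack([x_null, g])
    rss_null = _rss(y, x_null)
    rss_full = _rss(y, x_full)
    if rss_full <= 0 or rss_null <= 0:
        return 0.0, 0
    return max(n * np.log(rss_null / rss_full), 0.0), 1


def _rss(y, x):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def hurdle_de_test(cpm: np.ndarray, groups, detection_covariate=None,
                   min_cells: int = 10) -> pd.DataFrame:
    """Two-part hurdle differential expression between two cell groups.

    Parameters
    ----------
    cpm
        Genes x cells normalized CPM values (cells restricted to the two
        compared groups).
    groups
        Per-cell labels; exactly two distinct labels, the lexicographically
        larger one is treated as the "high" group for the fold-change sign
        unless labels are "high"/"low".
    detection_covariate
        Per-cell proportion of detected genes; computed from ``cpm`` when
        omitted.

    Returns a per-gene frame with ``log2fc`` (high minus low group mean of
    log2(CPM+1)), the LR statistic, its degrees of freedom, ``p_value`` and
    BH-adjusted ``p_adj``.  Genes undetected in all compared cells get NaN.
    """
    cpm = np.asarray(cpm, float)
    labels = np.asarray(groups)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("hurdle_de_test requires exactly two groups")
    if set(uniq) == {"high", "low"}:
        high_label = "high"
    else:
        high_label = uniq[-1]
    g = (labels == high_label).astype(float)
    if min(g.sum(), (1 - g).sum()) < min_cells:
        raise ValueError(f"each group needs at least {min_cells} cells")
    detected = cpm > 0
    cdr = (detection_covariate if detection_covariate is not None
           else detected.mean(axis=0))
    cdr = np.asarray(cdr, float)
    y_all = np.log2(cpm + 1.0)

    n_genes = cpm.shape[0]
    lr_stat = np.full(n_genes, np.nan)
    dfs = np.zeros(n_genes, int)
    log2fc = np.full(n_genes, np.nan)
    for gi in range(n_genes):
        z = detected[gi].astype(float)
        if z.sum() == 0:
            continue
        log2fc[gi] = y_all[gi, g == 1].mean() - y_all[gi, g == 0].mean()
        lr_d, df_d = _logistic_lr(z, g, cdr)
        det = detected[gi]
        lr_c, df_c = _gaussian_lr(y_all[gi, det], g[det], cdr[det])
        df = df_d + df_c
        if df == 0:
            continue
        lr_stat[gi] = lr_d + lr_c
        dfs[gi] = df
    p = np.full(n_genes, np.nan)
    ok = dfs > 0
    p[ok] = scipy.stats.chi2.sf(lr_stat[ok], dfs[ok])
    return pd.DataFrame({"log2fc": log2fc, "lr": lr_stat, "df": dfs,
                         "p_value": p, "p_adj": bh_adjust(p)})


def correlation_screen(cpm: np.ndarray, target, min_cells: int = 10) -> pd.DataFrame:
    """Spearman correlation of every gene with a per-cell target variable.

    Constant genes are excluded with a reason code; p values are two-sided
    (asymptotic t approximation) and BH-adjusted across tested genes.
    """
    cpm = np.asarray(cpm, float)
    t = np.asarray(target, float)
    n = t.size
    if n < min_cells:
        raise ValueError(f"correlation screen requires at least {min_cells} cells")
    const = cpm.min(axis=1) == cpm.max(axis=1)
    ranks = scipy.stats.rankdata(cpm, axis=1)
    tr = scipy.stats.rankdata(t)
    ranks_c = ranks - ranks.mean(axis=1, keepdims=True)
    tr_c = tr - tr.mean()
    denom = np.sqrt((ranks_c ** 2).sum(axis=1) * (tr_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, ranks_c @ tr_c / np.where(denom > 0, denom, 1.0), np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    rho[const] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p[const] = np.nan
    return pd.DataFrame({"rho": rho, "p_value": p, "p_adj": bh_adjust(p),
                         "excluded": const,
                         "reason": np.where(const, "constant", "")})


def integrate_hits(results: dict, gene_annotation: pd.DataFrame,
                   min_support: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """Combine the eight screen results into a candidate-regulator table.

    ``results`` maps analysis names to per-gene frames indexed like
    ``gene_annotation`` with an effect column (``log2fc`` or ``rho``) and a
    BH-adjusted ``p_adj``.  A gene is retained when it is significant
    (``p_adj <= alpha``) in at least ``min_support`` analyses, is not a
    pseudogene, and is not an X-linked gene whose significant effects are
    negative (silencing consequence rather than cause).
    """
    n = len(gene_annotation)
    support = np.zeros(n, int)
    neg_support = np.zeros(n, int)
    out = pd.DataFrame({
        "gene_id": gene_annotation["gene_id"].to_numpy(),
        "name": gene_annotation["name"].to_numpy()
        if "name" in gene_annotation else gene_annotation["gene_id"].to_numpy(),
    })
    for key, frame in results.items():
        effect_col = "log2fc" if "log2fc" in frame.columns else "rho"
        eff = frame[effect_col].to_numpy(float)
        padj = frame["p_adj"].to_numpy(float)
        sig = np.isfinite(padj) & (padj <= alpha)
        support += sig
        neg_support += sig & (eff < 0)
        out[f"{key}_effect"] = eff
        out[f"{key}_p_adj"] = padj
        out[f"{key}_significant"] = sig
    is_pseudo = gene_annotation["is_pseudogene"].to_numpy(bool) \
        if "is_pseudogene" in gene_annotation else np.zeros(n, bool)
    is_x = gene_annotation["chromosome"].eq("chrX").to_numpy()
    x_negative = is_x & (neg_support > 0)
    reason = np.where(is_pseudo, "pseudogene",
                      np.where(x_negative, "x_linked_negative_effect", ""))
    out["support"] = support
    out["excluded_reason"] = reason
    out["retained"] = (support >= min_support) & ~is_pseudo & ~x_negative
    return out
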