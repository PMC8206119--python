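"""Deletion-line bulk RNA-seq and pyrosequencing allelic-ratio analyses.

Two engineered lines carry a ~773 kb deletion of the X-inactivation centre
on one allele (dXic_B6 on the B6 allele, dXic_Cast on Cast), forcing the
intact allele to become the inactive X.  Chromosome-wide silencing is
compared between lines through per-gene Xi:Xa count ratios (pseudocount
+1), individual genes through day-0-normalized allelic ratios, and
pyrosequencing assays through odds ratios of the percent-B6 signal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import deletion_length_kb
from .simulate import DELETION_B6, DELETION_CAST

#: Shared deleted-region mask: union of the two engineered intervals, so the
#: paired cross-line test uses one gene set.
DELETED_REGION = (min(DELETION_B6[0], DELETION_CAST[0]),
                  max(DELETION_B6[1], DELETION_CAST[1]))

LINES = ("dXic_B6", "dXic_Cast")


def _xi_is_b6(line: str) -> bool:
    # the intact allele is inactivated: Xi = B6 in the Cast-deletion line
    return line == "dXic_Cast"


def in_deleted_region(start, end=None, region=DELETED_REGION) -> np.ndarray:
    """Whether gene coordinates overlap the deleted-region mask."""
    start = np.asarray(start)
    end = start if end is None else np.asarray(end)
    lo, hi = region
    return (end >= lo) & (start <= hi)


def chromosome_ratio_test(table: pd.DataFrame, day, min_as_counts: int = 50,
                          region_flag: str = "in_deleted_region"):
    """Per-gene Xi:Xa ratios per line at one day, plus the paired t test.

    Counts are summed across replicates per line; ``r_g = (sum e_Xi + 1) /
    (sum e_Xa + 1)`` with Xi the intact allele of each line.  Genes in the
    deleted region, and genes with fewer than ``min_as_counts`` summed
    allele-assignable counts in either line, are excluded; the surviving
    gene set is shared so the cross-line test is paired.

    Returns ``(ratios, p_value)`` where ``ratios`` has one row per gene and
    columns ``r_dXic_B6`` / ``r_dXic_Cast``.
    """
    sub = table[table["day"] == day]
    per_line = {}
    for line in LINES:
        grp = sub[sub["line"] == line].groupby("gene_id")[["e_B6", "e_Cast"]].sum()
        per_line[line] = grp
    genes = per_line[LINES[0]].index.intersection(per_line[LINES[1]].index)
    if region_flag in table.columns:
        flagged = table.groupby("gene_id")[region_flag].any()
        genes = genes[~flagged.reindex(genes).fillna(False).to_numpy(bool)]
    keep = []
    for g in genes:
        ok = True
        for line in LINES:
            row = per_line[line].loc[g]
            if row["e_B6"] + row["e_Cast"] < min_as_counts:
                ok = False
        if ok:
            keep.append(g)
    if len(keep) < 2:
        raise ValueError("fewer than two genes pass the bulk ratio filters")
    rows = {}
    for line in LINES:
        sums = per_line[line].loc[keep]
        if _xi_is_b6(line):
            r = (sums["e_B6"] + 1.0) / (sums["e_Cast"] + 1.0)
        else:
            r = (sums["e_Cast"] + 1.0) / (sums["e_B6"] + 1.0)
        rows[f"r_{line}"] = r
    ratios = pd.DataFrame(rows)
    t = scipy.stats.ttest_rel(ratios[f"r_{LINES[0]}"], ratios[f"r_{LINES[1]}"])
    return ratios, float(t.pvalue)


def gene_deletion_ratio(table: pd.DataFrame, gene, normalize_day0: bool = True):
    """Per-sample Xi:Xa ratio of one gene, day-0 normalized, plus t tests.

    The ratio is ``e_B6/e_Cast`` in dXic_Cast samples and ``e_Cast/e_B6``
    in dXic_B6 samples (the Xi allele over the Xa allele), optionally
    divided by the line's mean day-0 ratio.  Returns ``(samples, tests)``:
    per-sample normalized ratios and per-day two-sample t tests between the
    lines.
    """
    sub = table[(table["gene_id"] == gene) | (table["name"] == gene)].copy()
    if sub.empty:
        raise KeyError(f"gene not found in bulk table: {gene}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(sub["line"] == "dXic_Cast",
                     sub["e_B6"] / sub["e_Cast"].replace(0, np.nan),
                     sub["e_Cast"] / sub["e_B6"].replace(0, np.nan))
    sub["ratio"] = r
    if normalize_day0:
        day0 = sub[sub["day"] == 0].groupby("line")["ratio"].mean()
        if day0.isna().any() or (day0 <= 0).any():
            raise ValueError("day-0 ratios unavailable for normalization")
        sub["ratio"] = sub["ratio"] / sub["line"].map(day0)
    tests = []
    for day, grp in sub.groupby("day"):
        a = grp.loc[grp["line"] == LINES[0], "ratio"].dropna()
        b = grp.loc[grp["line"] == LINES[1], "ratio"].dropna()
        p = (float(scipy.stats.ttest_ind(a, b).pvalue)
             if min(len(a), len(b)) >= 2 else np.nan)
        tests.append((day, p))
    return sub, pd.DataFrame(tests, columns=["day", "p_value"])


def pyro_ratio(pyro: pd.DataFrame, gene=None, normalize_day0: bool = True,
               eps: float = 1e-6):
    """Pyrosequencing Xi:Xa odds ratios per sample, day-0 normalized.

    ``r = p/(1-p)`` in dXic_Cast samples and ``(1-p)/p`` in dXic_B6
    samples, with ``p`` the fraction of B6 molecules.  Values of p at 0 or
    1 are clipped to machine-safe bounds with a warning.
    """
    sub = pyro if gene is None else pyro[(pyro["gene_id"] == gene)
                                         | (pyro["name"] == gene)].copy()
    sub = sub.copy()
    p = sub["pct_B6"].to_numpy(float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("pct_B6 values at 0 or 1 clipped to machine-safe bounds")
        p = np.clip(p, eps, 1 - eps)
    odds = p / (1.0 - p)
    r = np.where(sub["line"] == "dXic_Cast", odds, 1.0 / odds)
    sub["ratio"] = r
    if normalize_day0:
        day0 = sub[sub["day"] == 0].groupby(["gene_id", "line"])["ratio"].mean()
        key = pd.MultiIndex.from_frame(sub[["gene_id", "line"]])
        sub["ratio"] = sub["ratio"].to_numpy() / day0.reindex(key).to_numpy()
    return sub


def pyro_tests(pyro_ratios: pd.DataFrame, differential_genes, stable_genes):
    """Cross-line tests of the normalized pyrosequencing ratios.

    Differential genes get per-gene, per-day unpaired two-sided t tests
    between the lines; the stable gene set is replicate-averaged and
    compared between lines with a Wilcoxon signed-rank test paired over
    (gene, day) combinations past day 0.
    """
    per_gene = []
    for gene in differential_genes:
        sub = pyro_ratios[(pyro_ratios["gene_id"] == gene)
                          | (pyro_ratios["name"] == gene)]
        for day, grp in sub[sub["day"] > 0].groupby("day"):
            a = grp.loc[grp["line"] == LINES[0], "ratio"].dropna()
            b = grp.loc[grp["line"] == LINES[1], "ratio"].dropna()
            p = (float(scipy.stats.ttest_ind(a, b).pvalue)
                 if min(len(a), len(b)) >= 2 else np.nan)
            per_gene.append((gene, day, p))
    per_gene = pd.DataFrame(per_gene, columns=["gene", "day", "p_value"])

    stable = pyro_ratios[pyro_ratios["gene_id"].isin(stable_genes)
                         | pyro_ratios["name"].isin(stable_genes)]
    means = (stable[stable["day"] > 0]
             .groupby(["gene_id", "day", "line"])["ratio"].mean().unstack("line"))
    means = means.dropna()
    if len(means) >= 2:
        w = scipy.stats.wilcoxon(means[LINES[0]], means[LINES[1]])
        stable_p = float(w.pvalue)
    else:
        stable_p = np.nan
    return per_gene, stable_p


def deletion_lengths_kb() -> dict:
    """Reported lengths of the two engineered deletions (kb)."""
    return {"dXic_B6": deletion_length_kb(*DELETION_B6),
            "dXic_Cast": deletion_length_kb(*DELETION_CAST)}
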