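"""Per-cell Xist expression-level and allelic-pattern classification.

Level classes use total Xist UMI counts: positive (> 5 UMIs), negative
(undetected), undetermined (1-5 UMIs).  Allelic patterns use the
allele-assignable Xist counts of cells with more than ``min_total`` such
counts: monoallelic (all counts one allele), biallelic (at least 20% of
counts from each allele), or skewed (minority allele below 20%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import AllelicCountSet

LEVEL_POSITIVE = "positive"
LEVEL_NEGATIVE = "negative"
LEVEL_UNDETERMINED = "undetermined"

MA_CLASSES = ("MA-B6", "MA-Cast")
SKEWED_CLASSES = ("skewed-B6", "skewed-Cast")


def classify_xist_level(xist_total_umi, threshold: int = 5):
    """Level class from total Xist UMIs: > threshold positive, 0 negative."""
    x = np.asarray(xist_total_umi)
    out = np.full(x.shape, LEVEL_UNDETERMINED, dtype=object)
    out[x > threshold] = LEVEL_POSITIVE
    out[x == 0] = LEVEL_NEGATIVE
    return out if out.ndim else out.item()


def classify_allelic_pattern(b6_umi, cast_umi, min_total: int = 5, ba_frac: float = 0.2):
    """Allelic Xist pattern from allele-assignable counts.

    Cells with ``b6 + cast <= min_total`` are unassignable.  Otherwise the
    minority-allele fraction decides: exactly 0 is monoallelic on the
    majority allele, at least ``ba_frac`` (inclusive) is biallelic, anything
    in between is skewed toward the majority allele.
    """
    b6 = np.atleast_1d(np.asarray(b6_umi, float))
    cast = np.atleast_1d(np.asarray(cast_umi, float))
    total = b6 + cast
    out = np.full(b6.shape, "unassignable", dtype=object)
    assignable = total > min_total
    with np.errstate(invalid="ignore", divide="ignore"):
        minority = np.where(total > 0, np.minimum(b6, cast) / np.maximum(total, 1), np.nan)
    major_b6 = b6 >= cast
    ma = assignable & (minority == 0)
    ba = assignable & (minority >= ba_frac)
    sk = assignable & ~ma & ~ba
    out[ma & major_b6] = "MA-B6"
    out[ma & ~major_b6] = "MA-Cast"
    out[ba] = "BA"
    out[sk & major_b6] = "skewed-B6"
    out[sk & ~major_b6] = "skewed-Cast"
    if np.isscalar(b6_umi) and np.isscalar(cast_umi):
        return out.item()
    return out


def classify_cells(dataset: AllelicCountSet, level_threshold: int = 5,
                   min_total: int = 5, ba_frac: float = 0.2) -> pd.DataFrame:
    """Classify every cell; returns one row per cell.

    Columns: ``xist_total_umi``, ``xist_b6_umi``, ``xist_cast_umi``,
    ``b6_fraction``, ``level_class``, ``allelic_class`` and ``xi_allele``
    (the Xist-expressing allele of strictly monoallelic cells, else NaN).
    """
    total = dataset.xist_counts("total")
    b6 = dataset.xist_counts("spliced_B6")
    cast = dataset.xist_counts("spliced_Cast")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(b6 + cast > 0, b6 / np.maximum(b6 + cast, 1), np.nan)
    allelic = classify_allelic_pattern(b6, cast, min_total=min_total, ba_frac=ba_frac)
    xi = np.where(allelic == "MA-B6", "B6",
                  np.where(allelic == "MA-Cast", "Cast", "none")).astype(object)
    return pd.DataFrame({
        "cell_id": dataset.cells["cell_id"],
        "time_point_days": dataset.cells["time_point_days"],
        "xist_total_umi": total.astype(int),
        "xist_b6_umi": b6.astype(int),
        "xist_cast_umi": cast.astype(int),
        "b6_fraction": frac,
        "level_class": classify_xist_level(total, threshold=level_threshold),
        "allelic_class": allelic,
        "xi_allele": xi,
    })


def pattern_time_summary(classification: pd.DataFrame) -> pd.DataFrame:
    """Per-day class fractions among cells with an assigned allelic pattern."""
    assigned = classification[classification["allelic_class"] != "unassignable"]
    rows = []
    for day, grp in assigned.groupby("time_point_days"):
        counts = grp["allelic_class"].value_counts()
        n = int(counts.sum())
        for cls, cnt in counts.items():
            rows.append((day, cls, int(cnt), cnt / n if n else 0.0))
    return pd.DataFrame(rows, columns=["time_point_days", "allelic_class", "n_cells",
                                       "fraction"])


def allelic_xist_levels(classification: pd.DataFrame, min_cells: int = 2) -> pd.DataFrame:
    """Compare Xist levels between MA-B6 and MA-Cast cells per day.

    Returns per-day median allelic Xist UMI counts per Xi allele and the
    two-sided Mann-Whitney rank-sum p value; days where either group has
    fewer than ``min_cells`` cells are flagged ``low_n`` and given p = 1.
    """
    ma = classification[classification["allelic_class"].isin(MA_CLASSES)]
    rows = []
    for day, grp in ma.groupby("time_point_days"):
        b6 = grp.loc[grp["allelic_class"] == "MA-B6", "xist_b6_umi"].to_numpy()
        cast = grp.loc[grp["allelic_class"] == "MA-Cast", "xist_cast_umi"].to_numpy()
        low_n = min(b6.size, cast.size) < min_cells
        if low_n:
            p = 1.0
        else:
            p = float(scipy.stats.mannwhitneyu(b6, cast, alternative="two-sided").pvalue)
        rows.append((day, b6.size, cast.size,
                     float(np.median(b6)) if b6.size else np.nan,
                     float(np.median(cast)) if cast.size else np.nan, p, low_n))
    return pd.DataFrame(rows, columns=["time_point_days", "n_MA_B6", "n_MA_Cast",
                                       "median_B6", "median_Cast", "p_value", "low_n"])
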