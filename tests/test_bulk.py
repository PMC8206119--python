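import numpy as np
import pandas as pd
import pytest

from axci.bulk import (DELETED_REGION, chromosome_ratio_test, deletion_lengths_kb,
                       gene_deletion_ratio, in_deleted_region, pyro_ratio, pyro_tests)
from axci.dataset import deletion_length_kb


def test_printed_deletion_coordinates_round_to_773_kb():
    assert deletion_lengths_kb() == {"dXic_B6": 773, "dXic_Cast": 773}
    assert deletion_length_kb(103_182_701, 103_955_531) == 773


def _bulk_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "name", "line", "replicate", "day",
                                       "e_B6", "e_Cast", "in_deleted_region"])


class TestChromosomeRatio:
    def test_ratio_arithmetic_with_plus_one(self):
        rows = []
        for gene, b6, cast in (("g1", 9, 19), ("g2", 49, 49)):
            for line in ("dXic_B6", "dXic_Cast"):
                rows.append((gene, gene, line, 0, 4, b6, cast, False))
        ratios, p = chromosome_ratio_test(_bulk_table(rows), day=4, min_as_counts=10)
        # dXic_Cast: Xi = B6 -> (9+1)/(19+1) = 0.5
        assert ratios.loc["g1", "r_dXic_Cast"] == pytest.approx(0.5)
        assert ratios.loc["g1", "r_dXic_B6"] == pytest.approx(2.0)

    def test_low_count_gene_excluded(self):
        rows = []
        for gene, b6, cast in (("lo", 24, 25), ("hi1", 60, 60), ("hi2", 80, 40)):
            for line in ("dXic_B6", "dXic_Cast"):
                rows.append((gene, gene, line, 0, 2, b6, cast, False))
        ratios, _ = chromosome_ratio_test(_bulk_table(rows), day=2, min_as_counts=50)
        assert "lo" not in ratios.index  # 49 summed counts < 50

    def test_deleted_region_genes_excluded(self):
        rows = []
        for gene, flag in (("in", True), ("out1", False), ("out2", False)):
            for line in ("dXic_B6", "dXic_Cast"):
                rows.append((gene, gene, line, 0, 2, 60, 60, flag))
        ratios, _ = chromosome_ratio_test(_bulk_table(rows), day=2)
        assert "in" not in ratios.index

    def test_line_symmetry(self):
        """Swapping allele and line labels simultaneously leaves ratios invariant."""
        rows = []
        rng = np.random.default_rng(0)
        for g in range(5):
            b6, cast = rng.integers(50, 200, 2)
            for line in ("dXic_B6", "dXic_Cast"):
                rows.append((f"g{g}", f"g{g}", line, 0, 3, b6, cast, False))
        table = _bulk_table(rows)
        swapped = table.copy()
        swapped["line"] = swapped["line"].map(
            {"dXic_B6": "dXic_Cast", "dXic_Cast": "dXic_B6"})
        swapped = swapped.rename(columns={"e_B6": "e_Cast", "e_Cast": "e_B6"})
        r1, _ = chromosome_ratio_test(table, day=3)
        r2, _ = chromosome_ratio_test(swapped, day=3)
        assert np.allclose(r1["r_dXic_B6"], r2["r_dXic_Cast"])
        assert np.allclose(r1["r_dXic_Cast"], r2["r_dXic_B6"])


class TestGeneRatio:
    def _table(self):
        rows = []
        for line, day, b6, cast in (
            ("dXic_Cast", 0, 10, 10), ("dXic_Cast", 2, 20, 10),
            ("dXic_B6", 0, 10, 10), ("dXic_B6", 2, 10, 30),
        ):
            for rep in range(2):
                rows.append(("g1", "g1", line, rep, day, b6, cast, False))
        return _bulk_table(rows)

    def test_branch_arithmetic(self):
        samples, _ = gene_deletion_ratio(self._table(), "g1", normalize_day0=False)
        cast_line = samples[(samples["line"] == "dXic_Cast") & (samples["day"] == 2)]
        assert np.allclose(cast_line["ratio"], 2.0)  # e_B6/e_Cast
        b6_line = samples[(samples["line"] == "dXic_B6") & (samples["day"] == 2)]
        assert np.allclose(b6_line["ratio"], 3.0)  # e_Cast/e_B6

    def test_day0_normalization(self):
        rows = []
        for rep in range(2):
            rows.append(("g1", "g1", "dXic_Cast", rep, 0, 20, 10, False))  # ratio 2
            rows.append(("g1", "g1", "dXic_Cast", rep, 2, 10, 10, False))  # ratio 1
            rows.append(("g1", "g1", "dXic_B6", rep, 0, 10, 10, False))
            rows.append(("g1", "g1", "dXic_B6", rep, 2, 10, 10, False))
        samples, _ = gene_deletion_ratio(_bulk_table(rows), "g1")
        late = samples[(samples["line"] == "dXic_Cast") & (samples["day"] == 2)]
        assert np.allclose(late["ratio"], 0.5)  # 1.0 / day-0 mean of 2.0

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError):
            gene_deletion_ratio(self._table(), "nope")


class TestPyro:
    def _pyro(self, p, line):
        return pd.DataFrame({"gene_id": ["g1"], "name": ["g1"], "line": [line],
                             "replicate": [0], "day": [2], "pct_B6": [p]})

    @pytest.mark.parametrize("p,line,expected", [
        (0.8, "dXic_Cast", 4.0),
        (0.5, "dXic_Cast", 1.0),
        (0.5, "dXic_B6", 1.0),
        (0.2, "dXic_B6", 4.0),
    ])
    def test_odds_arithmetic(self, p, line, expected):
        out = pyro_ratio(self._pyro(p, line), normalize_day0=False)
        assert out["ratio"].iloc[0] == pytest.approx(expected)

    def test_boundary_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = pyro_ratio(self._pyro(1.0, "dXic_Cast"), normalize_day0=False)
        assert np.isfinite(out["ratio"].iloc[0])

    def test_stable_gene_wilcoxon_runs(self):
        rng = np.random.default_rng(0)
        rows = []
        for gene in ("s1", "s2", "s3", "s4", "s5"):
            for line in ("dXic_B6", "dXic_Cast"):
                for day in (0, 2, 4):
                    for rep in range(3):
                        rows.append((gene, gene, line, rep, day,
                                     np.clip(rng.normal(0.5, 0.02), 0.05, 0.95)))
        pyro = pd.DataFrame(rows, columns=["gene_id", "name", "line", "replicate",
                                           "day", "pct_B6"])
        ratios = pyro_ratio(pyro)
        per_gene, stable_p = pyro_tests(ratios, differential_genes=["s1"],
                                        stable_genes=["s2", "s3", "s4", "s5"])
        assert np.isfinite(stable_p)
        assert set(per_gene["gene"]) == {"s1"}


def test_region_mask_union():
    lo, hi = DELETED_REGION
    assert lo == 103_182_257 and hi == 103_955_698
    assert in_deleted_region(103_500_000)
    assert not in_deleted_region(104_000_000)


def test_bulk_single_bin_consistency_with_single_cell_ratio():
    """With one replicate the bulk ratio equals the pooled single-cell ratio
    up to the pseudocount difference (+1 vs +0.01)."""
    xi_counts, xa_counts = 400, 1000
    bulk_r = (xi_counts + 1) / (xa_counts + 1)
    sc_r = (xi_counts + 0.01) / (xa_counts + 0.01)
    assert bulk_r == pytest.approx(sc_r, rel=2e-3)
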