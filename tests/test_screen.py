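import numpy as np
import pandas as pd
import pytest

from axci.screen import (bh_adjust, correlation_screen, hurdle_de_test,
                         integrate_hits, kmeans_group_cells)


def brute_force_bh(p):
    """O(n^2) step-up reference: independent of the vectorized implementation."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    for i in range(n):
        candidates = [p[order[j]] * n / (j + 1) for j in range(i, n)]
        adj_sorted[i] = min(1.0, min(candidates))
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(1, 50)
        p = rng.uniform(0, 1, n)
        assert np.allclose(bh_adjust(p), brute_force_bh(p))


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 500)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(bh_adjust(p), ref)


class TestKmeansGrouping:
    def test_well_separated_clusters_recovered(self):
        values = np.array([0.0] * 50 + [10.0] * 50 + [20.0] * 50)
        ga = kmeans_group_cells(values, k=3, n_top=1, n_bottom=1, min_cells=50)
        assert (ga.group[values == 20.0] == "high").all()
        assert (ga.group[values == 0.0] == "low").all()
        assert (ga.group[values == 10.0] == "middle").all()
        assert ga.valid

    def test_constant_values_fatal(self):
        with pytest.raises(ValueError):
            kmeans_group_cells(np.ones(100), k=3)

    def test_undersized_group_flagged_invalid(self):
        values = np.array([0.0] * 40 + [10.0] * 60 + [20.0] * 60)
        ga = kmeans_group_cells(values, k=3, n_top=1, n_bottom=1, min_cells=50)
        assert not ga.valid


class TestHurdle:
    def test_identical_expression_gives_p_one(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5, 40).astype(float)
        cpm = np.vstack([np.concatenate([base, base])])
        groups = np.array(["high"] * 40 + ["low"] * 40)
        cdr = np.concatenate([base, base]) * 0 + 0.5
        res = hurdle_de_test(cpm, groups, detection_covariate=cdr)
        assert res["p_value"].iloc[0] > 0.99

    def test_undetected_gene_skipped(self):
        cpm = np.zeros((1, 40))
        groups = np.array(["high"] * 20 + ["low"] * 20)
        res = hurdle_de_test(cpm, groups, detection_covariate=np.full(40, 0.5))
        assert np.isnan(res["p_value"].iloc[0])

    def test_minimum_group_size_enforced(self):
        cpm = np.ones((1, 15))
        groups = np.array(["high"] * 5 + ["low"] * 10)
        with pytest.raises(ValueError, match="at least"):
            hurdle_de_test(cpm, groups)

    def test_planted_shift_is_detected_with_correct_sign(self):
        rng = np.random.default_rng(2)
        n = 100
        low = rng.poisson(5, n)
        high = rng.poisson(20, n)
        cpm = np.vstack([np.concatenate([high, low])]).astype(float)
        groups = np.array(["high"] * n + ["low"] * n)
        res = hurdle_de_test(cpm, groups, detection_covariate=np.full(2 * n, 0.5))
        assert res["p_value"].iloc[0] < 1e-6
        assert res["log2fc"].iloc[0] > 0  # high minus low convention


class TestCorrelation:
    def test_perfect_monotone_correlations(self):
        target = np.arange(20.0)
        cpm = np.vstack([target, target[::-1], np.ones(20)])
        res = correlation_screen(cpm, target)
        assert res["rho"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] == 0.0
        assert res["rho"].iloc[1] == pytest.approx(-1.0)
        assert res["excluded"].iloc[2]
        assert res["reason"].iloc[2] == "constant"

    def test_matches_scipy_spearman(self):
        import scipy.stats
        rng = np.random.default_rng(3)
        cpm = rng.poisson(5, size=(20, 60)).astype(float)
        target = rng.normal(size=60)
        res = correlation_screen(cpm, target)
        for gi in range(20):
            if res["excluded"].iloc[gi]:
                continue
            ref = scipy.stats.spearmanr(cpm[gi], target)
            assert res["rho"].iloc[gi] == pytest.approx(ref.statistic, abs=1e-12)
            assert res["p_value"].iloc[gi] == pytest.approx(ref.pvalue, rel=1e-6)


class TestIntegration:
    def _annotation(self):
        return pd.DataFrame({
            "gene_id": ["a", "b", "x1", "p1"],
            "name": ["a", "b", "x1", "p1"],
            "chromosome": ["chr1", "chr2", "chrX", "chr3"],
            "is_pseudogene": [False, False, False, True],
        })

    def _results(self, sig_map):
        out = {}
        for k in range(8):
            name = f"an{k}"
            eff, padj = [], []
            for gene in ["a", "b", "x1", "p1"]:
                s = sig_map.get(gene, [])
                if k < len(s) and s[k] is not None:
                    eff.append(s[k])
                    padj.append(0.01)
                else:
                    eff.append(0.0)
                    padj.append(0.9)
            out[name] = pd.DataFrame({"log2fc": eff, "p_adj": padj})
        return out

    def test_support_threshold(self):
        res = self._results({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0]})
        hits = integrate_hits(res, self._annotation(), min_support=3)
        hits = hits.set_index("gene_id")
        assert hits.loc["a", "retained"]
        assert not hits.loc["b", "retained"]
        assert hits.loc["a", "support"] == 3

    def test_pseudogene_and_negative_x_excluded(self):
        res = self._results({"x1": [-1.0, -1.0, -1.0], "p1": [1.0, 1.0, 1.0]})
        hits = integrate_hits(res, self._annotation(), min_support=3).set_index("gene_id")
        assert not hits.loc["x1", "retained"]
        assert hits.loc["x1", "excluded_reason"] == "x_linked_negative_effect"
        assert not hits.loc["p1", "retained"]
        assert hits.loc["p1", "excluded_reason"] == "pseudogene"

    def test_positive_x_gene_retained(self):
        res = self._results({"x1": [1.0, 1.0, 1.0]})
        hits = integrate_hits(res, self._annotation(), min_support=3).set_index("gene_id")
        assert hits.loc["x1", "retained"]


def test_planted_repressor_recovered_in_pipeline_screen(default_sim, tmp_path):
    """The gene gating the Xist hazard reaches support >= 3 of 8; null genes do not."""
    import dataclasses

    from axci.pipeline import PipelineConfig, run_pipeline
    from axci.io import write_allelic_counts

    ds, tr = default_sim
    write_allelic_counts(ds, tmp_path / "counts")
    cfg = PipelineConfig(seed=1, stages=("qc", "normalize", "classify", "velocity",
                                         "regulators"))
    res = run_pipeline(cfg, tmp_path / "run", input_dir=tmp_path / "counts")
    hits = res["regulators"]["hits"].set_index("name")
    assert hits.loc["Nanog", "support"] >= 3
    assert hits.loc["Nanog", "retained"]
    # null rate judged on autosomal genes: X-linked genes are silenced by the
    # process itself and legitimately anti-correlate with Xist
    ds_genes = res["dataset"].genes.set_index("name")
    autosomal = hits.index[~ds_genes.loc[hits.index, "chromosome"].eq("chrX")]
    null_rate = (hits.loc[autosomal.drop("Nanog"), "support"] >= 3).mean()
    assert null_rate <= 0.05
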