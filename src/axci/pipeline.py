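"""End-to-end pipeline orchestration with reproducible per-stage seeding.

Stages run in dependency order (qc -> normalize -> classify -> velocity ->
regulators, and qc -> normalize -> classify -> silencing); every run writes
its stage outputs as TSVs plus a manifest recording the resolved
configuration, the per-stage seeds and a configuration hash, so two runs
with the same master seed produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import normalize as norm_mod
from . import qc as qc_mod
from . import screen as screen_mod
from . import silencing as sil_mod
from . import velocity as vel_mod
from . import xist as xist_mod
from .dataset import AllelicCountSet
from .io import read_allelic_counts, write_allelic_counts
from .simulate import SimulationParams, simulate_timecourse

ALL_STAGES = ("qc", "normalize", "classify", "velocity", "regulators", "silencing")


@dataclass
class PipelineConfig:
    """Every pipeline threshold, with its study default."""

    xist_umi_threshold: int = 5
    ba_frac: float = 0.2
    xo_bounds: tuple = (0.2, 0.8)
    gene_detect_frac: float = 0.2
    allelic_skew: float = 0.9
    mad_k: float = 3.0
    k_cells: int = 20
    fit_quantile: float = 0.025
    kmeans_k_xist: int = 7
    kmeans_k_deltax: int = 3
    kmeans_k_categories: int = 4
    min_group_cells: int = 50
    min_test_cells: int = 10
    min_support: int = 3
    n_bins: int = 10
    min_xp: float = 10.0
    min_cells_bin: int = 5
    min_as_counts: int = 25
    min_bins: int = 5
    n_boot: int = 1000
    alpha: float = 0.05
    screen_days: tuple = (1, 2)
    scaling_method: str = "median_ratio"
    stages: tuple = ALL_STAGES
    seed: int = 0
    simulate: bool = False
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seeds(master_seed: int, stages=ALL_STAGES) -> dict:
    """Derive one independent 31-bit seed per stage from a master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(stages))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(stages, children)}


def run_pipeline(config: PipelineConfig, out_dir, input_dir=None):
    """Run the configured stages; returns a dict of in-memory results.

    With ``config.simulate`` the input dataset is generated by the
    simulator (seeded from the master seed); otherwise ``input_dir`` must
    point to a dataset directory in the exchange format.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    results = {"config": config}

    if config.simulate:
        params = dataclasses.replace(config.simulation, seed=config.seed)
        dataset, truth = simulate_timecourse(params)
        write_allelic_counts(dataset, out / "simulated_counts")
        truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
        truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        results["truth"] = truth
    elif input_dir is not None:
        dataset = read_allelic_counts(input_dir)
    else:
        raise ValueError("run_pipeline needs an input directory or simulate=True")
    results["dataset"] = dataset

    stages = tuple(config.stages)
    missing = set(stages) - set(ALL_STAGES)
    if missing:
        raise ValueError(f"unknown stages: {sorted(missing)}")

    if "qc" in stages:
        dataset, cell_report = qc_mod.filter_cells(
            dataset, mad_k=config.mad_k, xo_bounds=config.xo_bounds)
        dataset, gene_report = qc_mod.filter_genes(
            dataset, detect_frac=config.gene_detect_frac,
            allelic_skew=config.allelic_skew)
        cell_report.to_frame().to_csv(out / "qc_cells.tsv", sep="\t", index=False)
        gene_report.to_frame().to_csv(out / "qc_genes.tsv", sep="\t", index=False)
        results["qc"] = {"cells": cell_report, "genes": gene_report}
        results["dataset"] = dataset

    norm = None
    if "normalize" in stages:
        _require(stages, "normalize", "qc")
        factors = norm_mod.compute_scaling_factors(dataset, method=config.scaling_method)
        norm = norm_mod.cpm_normalize(dataset, factors)
        pd.DataFrame({"cell_id": dataset.cells["cell_id"],
                      "scaling_factor": factors}).to_csv(
            out / "scaling_factors.tsv", sep="\t", index=False)
        results["norm"] = norm

    classification = None
    if "classify" in stages:
        _require(stages, "classify", "qc")
        classification = xist_mod.classify_cells(
            dataset, level_threshold=config.xist_umi_threshold,
            min_total=config.xist_umi_threshold, ba_frac=config.ba_frac)
        classification.to_csv(out / "xist_classification.tsv", sep="\t", index=False)
        xist_mod.pattern_time_summary(classification).to_csv(
            out / "xist_pattern_summary.tsv", sep="\t", index=False)
        results["classification"] = classification

    deltax = None
    if "velocity" in stages:
        _require(stages, "velocity", "normalize")
        fit, deltax, embedding, displacement = vel_mod.velocity_from_dataset(
            dataset, norm, k_cells=config.k_cells, fit_quantile=config.fit_quantile)
        pd.DataFrame({"gene_id": dataset.genes["gene_id"],
                      "gamma": fit.gamma, "fitted": fit.fitted}).to_csv(
            out / "velocity_gamma.tsv", sep="\t", index=False)
        pd.DataFrame({"cell_id": dataset.cells["cell_id"], "delta_x": deltax,
                      "pc1": embedding[:, 0], "pc2": embedding[:, 1],
                      "dpc1": displacement[:, 0], "dpc2": displacement[:, 1]}).to_csv(
            out / "velocity_cells.tsv", sep="\t", index=False)
        results["velocity"] = {"fit": fit, "deltax": deltax}

    if "regulators" in stages:
        _require(stages, "regulators", "classify")
        _require(stages, "regulators", "velocity")
        results["regulators"] = _regulator_stage(
            dataset, norm, classification, deltax, config, seeds["regulators"], out)

    if "silencing" in stages:
        _require(stages, "silencing", "classify")
        fits, differential = sil_mod.fit_silencing_table(
            dataset, classification, n_bins=config.n_bins, min_xp=config.min_xp,
            min_cells=config.min_cells_bin, min_as_counts=config.min_as_counts,
            min_bins=config.min_bins, kmeans_seed=seeds["silencing"],
            alpha=config.alpha)
        fits.to_csv(out / "silencing_fits.tsv", sep="\t", index=False)
        differential.to_csv(out / "silencing_differential.tsv", sep="\t", index=False)
        results["silencing"] = {"fits": fits, "differential": differential}

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "stages_run": list(stages),
        "n_genes": int(dataset.n_genes),
        "n_cells": int(dataset.n_cells),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def _require(stages, stage, dependency):
    if dependency not in stages:
        raise ValueError(f"stage '{stage}' requires stage '{dependency}' "
                         f"(missing from {list(stages)})")


def _regulator_stage(dataset, norm, classification, deltax, config, seed, out):
    """The eight screens (Xist/dX x requested days x DE/correlation)."""
    cpm = norm.layer("total")
    xist_cpm = cpm[dataset.xist_index()]
    gene_rows = ~dataset.genes["name"].eq("Xist").to_numpy()
    annotation = dataset.genes.loc[gene_rows].reset_index(drop=True)
    detected_frac = (cpm > 0).mean(axis=0)
    days = dataset.cells["time_point_days"].to_numpy()
    analyses = {}
    skipped = []
    for day in config.screen_days:
        if day == 0:
            raise ValueError("regulator screens exclude day 0 (pre-differentiation)")
        in_day = days == day
        for var, values, k, n_sel in (
            ("xist", np.log10(xist_cpm + 1.0), config.kmeans_k_xist, 3),
            ("deltax", np.log2(np.where(np.isfinite(deltax) & (deltax > 0),
                                        deltax, np.nan)), config.kmeans_k_deltax, 1),
        ):
            vals = values[in_day]
            usable = np.isfinite(vals)
            cells_idx = np.flatnonzero(in_day)[usable]
            key_de = f"{var}_day{day}_de"
            key_corr = f"{var}_day{day}_corr"
            try:
                grouping = screen_mod.kmeans_group_cells(
                    vals[usable], k=k, n_top=n_sel, n_bottom=n_sel,
                    min_cells=config.min_group_cells, seed=seed)
            except ValueError:
                skipped.append((key_de, "kmeans_failed"))
                grouping = None
            if grouping is not None and grouping.valid:
                sel = grouping.group != "middle"
                sub_cells = cells_idx[sel]
                try:
                    de = screen_mod.hurdle_de_test(
                        cpm[gene_rows][:, sub_cells], grouping.group[sel],
                        detection_covariate=detected_frac[sub_cells],
                        min_cells=config.min_test_cells)
                    analyses[key_de] = de
                except ValueError as exc:
                    skipped.append((key_de, str(exc)))
            elif grouping is not None:
                skipped.append((key_de, "group below minimum size"))
            if cells_idx.size >= config.min_test_cells:
                analyses[key_corr] = screen_mod.correlation_screen(
                    cpm[gene_rows][:, cells_idx], values[cells_idx])
            else:
                skipped.append((key_corr, "too few cells"))
    hits = screen_mod.integrate_hits(analyses, annotation,
                                     min_support=config.min_support,
                                     alpha=config.alpha) if analyses else None
    if hits is not None:
        hits.to_csv(out / "regulator_hits.tsv", sep="\t", index=False)
    if skipped:
        pd.DataFrame(skipped, columns=["analysis", "reason"]).to_csv(
            out / "regulator_skipped.tsv", sep="\t", index=False)
    return {"analyses": analyses, "hits": hits, "skipped": skipped}
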