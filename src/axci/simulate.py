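"""Stochastic simulator of random X-chromosome inactivation time courses.

The generator emulates an allele-resolved scRNA-seq experiment in a female
B6 x Cast hybrid embryonic stem cell line differentiated for 0-4 days:

* Xist is upregulated independently on each allele with a per-day hazard
  (B6 > Cast, emulating the Xce bias), gated on differentiation onset.
* Each Xist-expressing allele silences its chromosome along a latent
  silencing clock; per-gene silencing follows ``2**(-k_g * P)`` where ``P``
  is the chromosome-wide progress in XP units, so true per-gene half-times
  are ``1 / k_g`` in exactly the units the downstream estimator uses.
* A silencing-mediated negative feedback acts through a designated X-linked
  Xist activator gene: once the activator is silenced below a threshold on
  both alleles of a biallelic cell, the later-upregulated allele turns Xist
  off, resolving the cell to a monoallelic state.
* Cells that fail to upregulate Xist undergo a mild chromosome-wide X
  upregulation over time.
* Detection applies ~30% molecule capture with negative-binomial noise, and
  only ~4% of molecules cover a strain SNP and are allele-assignable.

One autosomal gene (named ``Nanog``) acts as an Xist repressor: its
cell-specific expression level scales down the Xist upregulation hazard, so
regulator screens have a planted positive control.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import AllelicCountSet

ALLELES = ("B6", "Cast")

#: mm10 coordinates of the engineered Xic deletions (1-based).
DELETION_B6 = (103_182_701, 103_955_531)
DELETION_CAST = (103_182_257, 103_955_698)

ACTIVATOR_GENE = "Rlim"
REPRESSOR_GENE = "Nanog"

#: Headline molecule-count scale: ~400k mRNAs per ES cell, of which ~120k
#: are detected at 30% capture.
MRNA_PER_CELL = 400_000
DETECTED_PER_CELL = 120_000


@dataclass
class SimulationParams:
    """All tunable knobs of the simulator, with study-condition defaults."""

    n_cells_per_day: int = 300
    days: tuple = (0, 1, 2, 3, 4)
    n_genes_autosomal: int = 900
    n_genes_x: int = 100
    mrna_target: float = MRNA_PER_CELL  #: expected spliced molecules per cell
    baseline_sdlog: float = 1.2  #: spread of log-normal per-gene means
    x_expression_boost: float = 1.25  #: baseline X:A expression ratio
    basal_skew_sdlog: float = 0.25  #: per-gene B6:Cast skew, log-normal around 1
    hazard_b6: float = 0.45  #: Xist upregulation hazard per day, B6 allele
    hazard_cast: float = 0.30  #: Xist upregulation hazard per day, Cast allele
    onset_shape: float = 2.5  #: Weibull shape of the onset hazard (1 = memoryless);
    #: the hazard ramps with differentiation so upregulation concentrates at days 1-2
    frac_refractory: float = 0.12  #: cells that never upregulate Xist
    feedback_threshold: float = 0.3  #: activator fraction below which feedback fires
    activator_rate: float = 0.05  #: silencing rate of the activator gene (per XP unit)
    v_b6: float = 28.0  #: chromosome-wide silencing speed, XP units/day, B6 as Xi
    v_cast: float = 38.0  #: chromosome-wide silencing speed, XP units/day, Cast as Xi
    capture_efficiency: float = 0.30
    snp_rate_mean: float = 0.04  #: mean fraction of molecules that are allele-assignable
    snp_rate_concentration: float = 60.0
    xist_snp_rate: float = 0.35  #: Xist is long and SNP-dense; far above average
    unspliced_fraction: float = 0.15
    unspliced_lag_days: float = 0.5  #: spliced pool lags transcription by this much
    nb_size: float = 8.0  #: NB size parameter; math.inf gives the Poisson limit
    x_upregulation_day4: float = 1.26  #: X multiplier at day 4 in Xist-negative cells
    frac_fast: float = 0.30
    frac_intermediate: float = 0.35
    frac_slow: float = 0.25
    frac_escape: float = 0.10
    n_allele_escape_cast: int = 2  #: genes escaping on the Cast allele only
    n_allele_escape_b6: int = 1
    xist_level_b6: float = 280.0  #: plateau Xist molecules from the B6 allele
    xist_level_cast: float = 160.0
    xist_ramp: float = 2.0  #: per-day rate of the Xist expression ramp
    regulator_sd: float = 0.5  #: cell-to-cell log-sd of the repressor's level
    regulator_coupling: float = 3.0  #: hazard ~ repressor_level ** (-coupling); the
    #: Weibull onset maps this onto on-times as scale**(-coupling/onset_shape)
    cell_size_sdlog: float = 0.15
    bulk_replicates: int = 3
    bulk_depth_scale: float = 1.0
    pyro_concentration: float = 200.0  #: beta noise concentration of pyro assays
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for name in ("hazard_b6", "hazard_cast", "v_b6", "v_cast", "activator_rate"):
            if getattr(self, name) < 0:
                bad.append(name)
        for name in ("capture_efficiency", "snp_rate_mean", "unspliced_fraction",
                     "frac_fast", "frac_intermediate", "frac_slow", "frac_escape"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(name)
        if not 0.0 <= self.feedback_threshold < 1.0:
            bad.append("feedback_threshold")
        if self.frac_fast + self.frac_intermediate + self.frac_slow + self.frac_escape > 1.0 + 1e-9:
            bad.append("category fractions sum to > 1")
        if bad:
            raise ValueError(f"invalid simulation parameters: {', '.join(bad)}")

    @property
    def hazards(self):
        return {"B6": self.hazard_b6, "Cast": self.hazard_cast}

    @property
    def speeds(self):
        return {"B6": self.v_b6, "Cast": self.v_cast}


@dataclass
class SimulationTruth:
    """Latent ground truth emitted alongside the counts."""

    cells: pd.DataFrame  #: per cell: on/off times per allele, Xi call, true XP
    genes: pd.DataFrame  #: per gene: per-allele true rate/XP50/category, skew, SNP rate
    params: SimulationParams = None


# --------------------------------------------------------------------------- genes
def _build_genes(params: SimulationParams, rng: np.random.Generator):
    n_a, n_x = params.n_genes_autosomal, params.n_genes_x
    rows = []
    for i in range(n_a):
        chrom = f"chr{(i % 19) + 1}"
        start = 3_000_000 + 150_000 * (i // 19)
        rows.append((f"genA{i:04d}", f"genA{i:04d}", chrom, start, start + 20_000, False))
    x_named = [("Xist", 103_460_373, 103_483_233),
               (ACTIVATOR_GENE, 73_805_000, 73_830_000),
               ("Jpx", 103_629_000, 103_640_000),
               ("Ftx", 103_760_000, 103_830_000)]
    x_positions = np.linspace(5_000_000, 165_000_000, n_x)
    for i in range(n_x):
        if i < len(x_named):
            name, start, end = x_named[i]
        else:
            name = f"genX{i:04d}"
            start = int(x_positions[i])
            end = start + 20_000
        rows.append((name, name, "chrX", start, end, False))
    genes = pd.DataFrame(rows, columns=["gene_id", "name", "chromosome", "start", "end",
                                        "is_pseudogene"])
    # mark ~5% of autosomal genes as pseudogenes (never Nanog)
    pseudo = rng.random(len(genes)) < 0.05
    pseudo[genes["chromosome"].eq("chrX").to_numpy()] = False
    genes["is_pseudogene"] = pseudo
    # rename one autosomal non-pseudogene as the planted Xist repressor
    repressor_idx = int(np.flatnonzero(~pseudo & genes["chromosome"].ne("chrX"))[0])
    genes.loc[repressor_idx, ["gene_id", "name"]] = REPRESSOR_GENE
    return genes, repressor_idx


def _assign_rates(params: SimulationParams, genes: pd.DataFrame, rng: np.random.Generator,
                  detectability=None):
    """Per-gene, per-allele silencing rates k (per XP unit) and categories.

    ``detectability`` (expected allele-assignable counts per gene) steers the
    choice of allele-specific escapers toward well-detected genes, mirroring
    the robustly quantified differential escapers of real hybrid lines.
    """
    n = len(genes)
    is_x = genes["chromosome"].eq("chrX").to_numpy()
    is_xist = genes["name"].eq("Xist").to_numpy()
    k = np.zeros((n, 2))
    category = np.full((n, 2), "", dtype=object)
    x_idx = np.flatnonzero(is_x & ~is_xist)
    fractions = [params.frac_fast, params.frac_intermediate, params.frac_slow,
                 params.frac_escape]
    names = ["fast", "intermediate", "slow", "escape"]
    ranges = {"fast": (12.0, 35.0), "intermediate": (38.0, 62.0), "slow": (65.0, 95.0)}
    counts = np.floor(np.array(fractions) / sum(fractions) * x_idx.size).astype(int)
    counts[1] += x_idx.size - counts.sum()
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    for gi, lab in zip(x_idx, labels):
        if lab == "escape":
            k[gi] = 0.0
        else:
            lo, hi = ranges[lab]
            k[gi] = 1.0 / rng.uniform(lo, hi)
        category[gi] = lab
    # the activator silences fast on both alleles (drives the feedback)
    act = np.flatnonzero(genes["name"].eq(ACTIVATOR_GENE).to_numpy())
    if act.size:
        k[act[0]] = params.activator_rate
        category[act[0]] = "fast"
    # allele-specific escapers drawn from genes silencing on both alleles,
    # preferring well-detected genes when detectability is known; genes in
    # the Xic deletion interval are excluded so the escapers stay assayable
    # in the deletion-line validation
    region_lo = min(DELETION_B6[0], DELETION_CAST[0])
    region_hi = max(DELETION_B6[1], DELETION_CAST[1])
    starts = genes["start"].to_numpy()
    silencers = [gi for gi in x_idx
                 if category[gi, 0] in ("fast", "intermediate") and gi not in act
                 and not (region_lo <= starts[gi] <= region_hi)]
    if detectability is not None and silencers:
        det = np.asarray(detectability, float)
        cut = np.quantile(det[silencers], 0.67)
        preferred = [gi for gi in silencers if det[gi] >= cut]
        if len(preferred) >= params.n_allele_escape_cast + params.n_allele_escape_b6:
            silencers = preferred
        rng.shuffle(silencers)
    else:
        rng.shuffle(silencers)
    esc_cast = silencers[: params.n_allele_escape_cast]
    esc_b6 = silencers[params.n_allele_escape_cast:
                       params.n_allele_escape_cast + params.n_allele_escape_b6]
    for gi in esc_cast:  # escapes when the Cast allele is the Xi
        k[gi, 1] = 0.0
        category[gi, 1] = "escape"
    for gi in esc_b6:
        k[gi, 0] = 0.0
        category[gi, 0] = "escape"
    return k, category, np.array(esc_cast, int), np.array(esc_b6, int)


# ------------------------------------------------------------------- trajectories
def _progress(t: float, t_on: float, t_off, v: float) -> float:
    """Chromosome silencing progress (XP units, 0-100) at time ``t``.

    The latent clock advances linearly at ``v`` XP units per day while Xist
    is expressed (capped at 100) and runs back down after Xist is lost.
    """
    if not np.isfinite(t_on) or t <= t_on:
        return 0.0
    if t_off is None or t <= t_off:
        return min(100.0, v * (t - t_on))
    peak = min(100.0, v * (t_off - t_on))
    return max(0.0, peak - v * (t - t_off))  # reactivation after Xist loss


def simulate_xist_trajectory(t_sample: float, params: SimulationParams,
                             rng: np.random.Generator, hazard_scale: float = 1.0,
                             refractory: bool = False):
    """Draw per-allele Xist on/off times for one cell sampled at ``t_sample``.

    On-times follow a Weibull model gated on differentiation onset at time
    0: the cumulative hazard of allele ``a`` is ``h_a * t ** onset_shape``
    (``onset_shape = 1`` recovers the memoryless exponential), scaled by
    ``hazard_scale``.  Refractory cells never upregulate.  If both alleles
    are on and the activator gene has been silenced below the feedback
    threshold on both, the later-upregulated allele turns Xist off at the
    moment the second threshold crossing occurs.

    Returns ``{"B6": (on, off), "Cast": (on, off)}`` with ``math.inf`` for
    events that never happen.
    """
    on = {}
    for allele in ALLELES:
        h = params.hazards[allele] * hazard_scale
        if refractory or h <= 0:
            on[allele] = math.inf
        else:
            on[allele] = (rng.exponential(1.0) / h) ** (1.0 / params.onset_shape)
    off = {a: math.inf for a in ALLELES}
    if all(on[a] < t_sample for a in ALLELES):
        theta, k_act = params.feedback_threshold, params.activator_rate
        if theta > 0 and k_act > 0:
            p_star = -math.log2(theta) / k_act
            if p_star < 100.0:
                # time each allele's activator copy crosses the threshold
                cross = {a: on[a] + p_star / params.speeds[a] for a in ALLELES}
                t_fb = max(cross.values())
                if t_fb < t_sample:
                    later = max(ALLELES, key=lambda a: on[a])
                    off[later] = t_fb
    return {a: (on[a], off[a]) for a in ALLELES}


# ------------------------------------------------------------------------ counts
def _nb_sample(mean: np.ndarray, size: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draw with ``var = m + m^2/size``; Poisson as size -> inf."""
    mean = np.maximum(np.asarray(mean, float), 0.0)
    if not np.isfinite(size):
        return rng.poisson(mean)
    lam = rng.gamma(shape=size, scale=1.0 / size, size=mean.shape)
    return rng.poisson(mean * lam)


def sample_counts(mu_spliced: np.ndarray, mu_unspliced: np.ndarray,
                  snp_rates: np.ndarray, params: SimulationParams,
                  rng: np.random.Generator) -> dict:
    """Sample the five detected-count layers from expected molecule numbers.

    ``mu_spliced``/``mu_unspliced`` have shape ``(n_genes, n_cells, 2)``
    (alleles ordered B6, Cast).  Molecules are captured at
    ``capture_efficiency`` with NB noise; allele-assignable molecules are a
    binomial thinning of each allele's detected molecules at the per-gene
    SNP-coverage rate, which guarantees ``spliced_B6 + spliced_Cast <=
    total`` by construction.
    """
    cap = params.capture_efficiency
    det_s = np.stack([_nb_sample(cap * mu_spliced[:, :, a], params.nb_size, rng)
                      for a in range(2)], axis=2)
    det_u = np.stack([_nb_sample(cap * mu_unspliced[:, :, a], params.nb_size, rng)
                      for a in range(2)], axis=2)
    snp = np.clip(snp_rates, 0.0, 1.0)[:, None]
    layers = {
        "total": det_s.sum(axis=2),
        "spliced_B6": rng.binomial(det_s[:, :, 0], snp),
        "spliced_Cast": rng.binomial(det_s[:, :, 1], snp),
        "unspliced_B6": rng.binomial(det_u[:, :, 0], snp),
        "unspliced_Cast": rng.binomial(det_u[:, :, 1], snp),
    }
    return {k: sp.csr_matrix(v, dtype=np.int64) for k, v in layers.items()}


# -------------------------------------------------------------------- time course
def simulate_timecourse(params: SimulationParams = None):
    """Simulate the full differentiation time course.

    Returns
    -------
    (AllelicCountSet, SimulationTruth)
        Deterministic given ``params.seed``.
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    genes, repressor_idx = _build_genes(params, rng)
    n_genes = len(genes)
    is_x = genes["chromosome"].eq("chrX").to_numpy()
    xist_idx = int(np.flatnonzero(genes["name"].eq("Xist").to_numpy())[0])

    base = rng.lognormal(mean=0.0, sigma=params.baseline_sdlog, size=n_genes)
    base[is_x] *= params.x_expression_boost
    base[xist_idx] = 0.0
    base *= params.mrna_target / max(base.sum(), 1e-12)
    skew = rng.lognormal(mean=0.0, sigma=params.basal_skew_sdlog, size=n_genes)
    share = np.stack([skew / (1.0 + skew), 1.0 / (1.0 + skew)], axis=1)  # B6, Cast
    snp_rates = rng.beta(params.snp_rate_mean * params.snp_rate_concentration,
                         (1 - params.snp_rate_mean) * params.snp_rate_concentration,
                         size=n_genes)
    snp_rates[xist_idx] = params.xist_snp_rate

    k_rates, category, esc_cast, esc_b6 = _assign_rates(
        params, genes, rng, detectability=base * snp_rates)

    days = np.repeat(params.days, params.n_cells_per_day).astype(float)
    n_cells = days.size
    size_factor = rng.lognormal(0.0, params.cell_size_sdlog, size=n_cells)
    q_repressor = rng.lognormal(0.0, params.regulator_sd, size=n_cells)
    # refractory (never-upregulating) cells are preferentially high-repressor,
    # mirroring the retained pluripotency profile of Xist-negative cells;
    # weights keep the expected refractory fraction at frac_refractory
    w = q_repressor ** 2
    refractory = rng.random(n_cells) < np.clip(
        params.frac_refractory * w / np.exp(2 * params.regulator_sd ** 2), 0.0, 1.0)

    cell_rows = []
    prog_s = np.zeros((n_cells, 2))  # progress seen by the spliced pool (lagged)
    prog_u = np.zeros((n_cells, 2))  # progress seen by the unspliced pool
    xist_mu = np.zeros((n_cells, 2))
    lag = params.unspliced_lag_days
    for c in range(n_cells):
        t = days[c]
        scale = q_repressor[c] ** (-params.regulator_coupling)
        traj = simulate_xist_trajectory(t, params, rng, hazard_scale=scale,
                                        refractory=bool(refractory[c]))
        active = [a for a in ALLELES if traj[a][0] < t and traj[a][1] > t]
        for ai, allele in enumerate(ALLELES):
            on, off = traj[allele]
            off_arg = off if np.isfinite(off) else None
            v = params.speeds[allele]
            prog_u[c, ai] = _progress(t, on, off_arg, v)
            prog_s[c, ai] = _progress(t - lag, on, off_arg, v)
            if on < t and off > t:
                level = params.xist_level_b6 if allele == "B6" else params.xist_level_cast
                xist_mu[c, ai] = level * (1.0 - math.exp(-params.xist_ramp * (t - on)))
        if len(active) == 1:
            xi = active[0]
        elif len(active) == 2:
            xi = "BA"
        else:
            xi = "none"
        cell_rows.append({
            "cell_id": f"cell{c:05d}", "time_point_days": int(t),
            "on_time_B6": traj["B6"][0], "off_time_B6": traj["B6"][1],
            "on_time_Cast": traj["Cast"][0], "off_time_Cast": traj["Cast"][1],
            "xi_allele": xi, "repressor_level": q_repressor[c],
        })
    truth_cells = pd.DataFrame(cell_rows)

    # expected molecule numbers per gene / cell / allele
    mult_s = np.ones((n_genes, n_cells, 2))
    mult_u = np.ones((n_genes, n_cells, 2))
    xg = np.flatnonzero(is_x)
    for ai in range(2):
        mult_s[xg, :, ai] = 2.0 ** (-np.outer(k_rates[xg, ai], prog_s[:, ai]))
        mult_u[xg, :, ai] = 2.0 ** (-np.outer(k_rates[xg, ai], prog_u[:, ai]))
    negative = truth_cells["xi_allele"].eq("none").to_numpy()
    upreg = np.ones(n_cells)
    upreg[negative] = 1.0 + (params.x_upregulation_day4 - 1.0) * days[negative] / 4.0
    mult_s[xg] *= upreg[None, :, None]
    mult_u[xg] *= upreg[None, :, None]

    mu = base[:, None, None] * share[:, None, :]
    mu_s = mu * mult_s
    mu_u = params.unspliced_fraction * mu * mult_u
    mu_s[repressor_idx] *= q_repressor[:, None]
    mu_u[repressor_idx] *= q_repressor[:, None]
    mu_s[xist_idx] = xist_mu
    mu_u[xist_idx] = params.unspliced_fraction * xist_mu
    mu_s *= size_factor[None, :, None]
    mu_u *= size_factor[None, :, None]

    layers = sample_counts(mu_s, mu_u, snp_rates, params, rng)

    # true XP from the latent spliced expression (X genes except Xist)
    x_no_xist = is_x.copy()
    x_no_xist[xist_idx] = False
    lat = mu_s[x_no_xist].sum(axis=0)  # (n_cells, 2)
    true_xp = np.full(n_cells, np.nan)
    xi_allele = truth_cells["xi_allele"].to_numpy()
    for ai, allele in enumerate(ALLELES):
        m = xi_allele == allele
        xp = 100.0 * (1.0 - (lat[m, ai] + 0.01) / (lat[m, 1 - ai] + 0.01))
        true_xp[m] = np.clip(xp, 0.0, 100.0)
    truth_cells["true_xp"] = true_xp

    total = np.asarray(layers["total"].todense())
    n_umi = total.sum(axis=0)
    cells = pd.DataFrame({
        "cell_id": truth_cells["cell_id"],
        "time_point_days": truth_cells["time_point_days"],
        "n_umi": n_umi.astype(int),
        "n_reads": (n_umi * rng.lognormal(1.2, 0.1, size=n_cells)).astype(int),
        "n_genes": (total > 0).sum(axis=0).astype(int),
        "pct_mito": rng.gamma(4.0, 0.75, size=n_cells),
        "pct_ercc": rng.gamma(3.0, 0.6, size=n_cells),
        "dead_stain_intensity": rng.lognormal(3.0, 0.3, size=n_cells),
    })

    xp50 = np.where(k_rates > 0, 1.0 / np.maximum(k_rates, 1e-12), np.inf)
    xp50 = np.minimum(xp50, 100.0)
    truth_genes = pd.DataFrame({
        "gene_id": genes["gene_id"], "name": genes["name"],
        "chromosome": genes["chromosome"],
        "rate_B6": k_rates[:, 0], "rate_Cast": k_rates[:, 1],
        "true_xp50_B6": xp50[:, 0], "true_xp50_Cast": xp50[:, 1],
        "category_B6": category[:, 0], "category_Cast": category[:, 1],
        "basal_skew": skew, "snp_rate": snp_rates, "baseline_mean": base,
        "escapes_on_Cast": np.isin(np.arange(n_genes), esc_cast),
        "escapes_on_B6": np.isin(np.arange(n_genes), esc_b6),
    })
    truth_genes.loc[~is_x, ["true_xp50_B6", "true_xp50_Cast"]] = np.nan

    dataset = AllelicCountSet(genes, cells, layers)
    truth = SimulationTruth(cells=truth_cells, genes=truth_genes,
                            params=dataclasses.replace(params))
    return dataset, truth


# ------------------------------------------------------------------ bulk validation
def simulate_bulk_deletion(params: SimulationParams = None, rng=None,
                           truth: SimulationTruth = None):
    """Simulate bulk allele-specific RNA-seq of the two Xic deletion lines.

    In each line the allele carrying the Xic deletion cannot upregulate Xist,
    so the intact allele is inactivated deterministically with its
    chromosome-wide speed.  Genes inside the deleted interval have zero
    counts on the deleted allele.

    Returns a tidy table (gene, line, replicate, day, e_B6, e_Cast) for
    X-linked genes, plus the gene truth used (handy when ``truth`` is None).
    """
    params = params or SimulationParams()
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    if truth is None:
        genes, _ = _build_genes(params, rng)
        k_rates, category, _, _ = _assign_rates(params, genes, rng,
                                                detectability=None)
        skew = rng.lognormal(0.0, params.basal_skew_sdlog, size=len(genes))
        base = rng.lognormal(4.0, params.baseline_sdlog, size=len(genes))
    else:
        genes = pd.DataFrame({
            "gene_id": truth.genes["gene_id"], "name": truth.genes["name"],
            "chromosome": truth.genes["chromosome"],
            "start": 0, "end": 0, "is_pseudogene": False,
        })
        k_rates = truth.genes[["rate_B6", "rate_Cast"]].to_numpy()
        skew = truth.genes["basal_skew"].to_numpy()
        base = truth.genes["baseline_mean"].to_numpy(float).copy()
    # recover coordinates from the canonical gene builder for the region mask
    coords, _ = _build_genes(dataclasses.replace(params), np.random.default_rng(0))
    coord_map = coords.set_index("gene_id")[["start", "end"]]

    is_x = genes["chromosome"].eq("chrX").to_numpy()
    # rescale to bulk sequencing depth: the median X-linked gene gets ~300
    # allele-assignable counts per replicate
    x_base = base[is_x & (base > 0)]
    if x_base.size:
        base = base / np.median(x_base) * 300.0
    region = tuple(sorted({*DELETION_B6, *DELETION_CAST}))
    lo, hi = min(region), max(region)
    rows = []
    onset = 0.5  # days until Xist is up in the bulk population
    share_b6 = skew / (1.0 + skew)
    for line, deleted_ai in (("dXic_B6", 0), ("dXic_Cast", 1)):
        xi_ai = 1 - deleted_ai  # intact allele becomes the Xi
        v = params.speeds[ALLELES[xi_ai]]
        for day in params.days:
            prog = min(100.0, v * max(day - onset, 0.0))
            for rep in range(params.bulk_replicates):
                depth = params.bulk_depth_scale * rng.lognormal(0.0, 0.1)
                for gi in np.flatnonzero(is_x):
                    name = genes["name"].iloc[gi]
                    if name == "Xist":
                        continue
                    start = coord_map["start"].get(genes["gene_id"].iloc[gi], 0)
                    in_region = lo <= start <= hi
                    mu = np.array([base[gi] * share_b6[gi], base[gi] * (1 - share_b6[gi])])
                    mu[xi_ai] *= 2.0 ** (-k_rates[gi, xi_ai] * prog)
                    if in_region:
                        mu[deleted_ai] = 0.0
                    counts = _nb_sample(depth * mu, params.nb_size, rng)
                    rows.append((genes["gene_id"].iloc[gi], name, line, rep, day,
                                 int(counts[0]), int(counts[1]), bool(in_region)))
    table = pd.DataFrame(rows, columns=["gene_id", "name", "line", "replicate", "day",
                                        "e_B6", "e_Cast", "in_deleted_region"])
    return table


def simulate_pyro(params: SimulationParams = None, rng=None, bulk: pd.DataFrame = None,
                  genes=None):
    """Derive per-gene percent-B6 pyrosequencing tables from a bulk simulation.

    The observed fraction ``p`` is a beta-noised version of the bulk allelic
    proportion for each (gene, line, replicate, day).
    """
    params = params or SimulationParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    if bulk is None:
        bulk = simulate_bulk_deletion(params, rng=rng)
    if genes is not None:
        bulk = bulk[bulk["name"].isin(genes) | bulk["gene_id"].isin(genes)]
    conc = params.pyro_concentration
    tot = (bulk["e_B6"] + bulk["e_Cast"]).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_true = np.where(tot > 0, bulk["e_B6"].to_numpy() / np.maximum(tot, 1.0), 0.5)
    p_true = np.clip(p_true, 5e-3, 1 - 5e-3)  # assay noise floor
    p_obs = rng.beta(conc * p_true, conc * (1.0 - p_true))
    out = bulk[["gene_id", "name", "line", "replicate", "day"]].copy()
    out["pct_B6"] = p_obs
    return out
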