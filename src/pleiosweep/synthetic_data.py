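"""Forward-in-time simulator for the full pipeline input bundle.

A diploid Wright–Fisher population is simulated over a single multi-SNP
region: a common ancestral population splits into breeds that evolve
separately, a core variant experiences positive selection (fitness 1, 1+s,
1+2s per alt-allele copy) over the final generations, and crossbred
individuals are produced by inter-breed matings in the last generation.
Gametes recombine via a Poisson crossover process at a per-bp rate, so the
sweep drags linked founder haplotypes to high frequency — the mechanism
behind extended haplotype homozygosity around selected alleles.

Founder haplotypes are drawn site-independently at U-shaped allele
frequencies; LD in the output arises from drift, the breed split, admixture
and the sweep (no ancestral coalescent LD — a documented limitation).

On top of the haplotypes the module generates four correlated phenotypes
(height, weight, body condition score, and a binary puberty trait from a
liability threshold at a configured prevalence) with an antagonistic
pleiotropic QTL and a polygenic background, plus a cis-expression trait with
one or two planted eQTLs and its per-variant marginal summary statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cojo import marginal_ols_scan
from .genio import (
    HaplotypePanel,
    make_variant_table,
    write_phenotypes,
    write_vcf,
)

TRAITS = ("height", "weight", "bcs", "puberty")

DEFAULT_RESIDUAL_COR = (
    (1.0, 0.3, 0.2, 0.2),
    (0.3, 1.0, 0.2, 0.2),
    (0.2, 0.2, 1.0, 0.1),
    (0.2, 0.2, 0.1, 1.0),
)


class SweepLostError(RuntimeError):
    """The selected allele drifted out of the population."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic replicate (all units noted inline)."""

    seed: int = 0
    # population structure
    n_breeds: int = 2
    n_per_breed: int = 300  # diploids per breed (WF population size = cohort size)
    crossbred_fraction: float = 0.3  # crossbreds as a fraction of the final cohort
    # region
    chrom: str = "1"
    region_length: int = 2_000_000  # bp
    n_snps: int = 1_000
    recomb_rate: float = 1e-8  # crossovers per bp per meiosis (~1 cM/Mb)
    founder_freq_beta: float = 0.4  # Beta(a, a) founder allele frequencies
    # unlinked neutral background chromosome (stands in for the rest of the
    # genome: feeds the GRM, the genotype PCs and the polygenic background)
    background_chrom: str = "2"
    n_background_snps: int = 1_000
    background_length: int = 2_000_000  # bp
    # demography (generations)
    pre_split_generations: int = 10
    post_split_generations: int = 55
    # selective sweep at the core variant
    core_index: int | None = None  # defaults to the middle variant
    selection_coeff: float = 0.05  # fitness 1, 1+s, 1+2s
    sweep_generations: int = 50  # final generations of the post-split phase
    sweep_initial_freq: float = 0.2
    # pleiotropic QTL (alt-allele effects in residual-SD units; antagonistic:
    # the allele raising height/weight lowers BCS and delays puberty)
    qtl_index: int | None = None  # defaults to the core variant
    qtl_effects: tuple = (1.0, 1.0, -0.7, -0.8)
    h2: tuple = (0.3, 0.3, 0.3, 0.3)  # polygenic background heritability
    n_polygenic: int = 200
    residual_cor: tuple = DEFAULT_RESIDUAL_COR
    n_groups: int = 5  # contemporary groups (herd-year)
    group_effect_sd: float = 0.5
    puberty_prevalence: float = 0.42
    # cis expression
    gene_name: str = "GENE1"
    gene_start: int | None = None  # defaults to the core variant's position
    eqtl_index: int | None = None  # defaults to the core variant
    eqtl_effect: float = 1.5  # expression units per alt copy
    second_eqtl_index: int | None = None
    second_eqtl_effect: float = 0.0
    expression_noise_sd: float = 1.0
    mediated: bool = False  # trait QTL effects proportional to the expression effect
    record_founders: bool = False  # keep founder haplotypes in the truth record

    def __post_init__(self):
        if self.selection_coeff < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not (0 <= self.crossbred_fraction < 1):
            raise ValueError("crossbred fraction must lie in [0, 1)")
        if self.core_index is None:
            self.core_index = self.n_snps // 2
        if not 0 <= self.core_index < self.n_snps:
            raise ValueError("core index outside the region")
        if any(not (0 <= h < 1) for h in self.h2):
            raise ValueError("h2 must lie in [0, 1)")
        r = np.asarray(self.residual_cor, dtype=float)
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("residual correlation matrix must be positive definite")


@dataclass
class SimTruth:
    """Ground truth recorded per replicate, sufficient to score recovery."""

    core_id: str = ""
    qtl_id: str = ""
    qtl_effects: dict = field(default_factory=dict)
    sweep_trajectory: list = field(default_factory=list)  # core alt freq per generation
    final_core_freq: float = 0.0
    breed_of_sample: dict = field(default_factory=dict)
    realized_h2: dict = field(default_factory=dict)
    puberty_threshold: float = 0.0
    realized_prevalence: float = 0.0
    eqtl_truth: list = field(default_factory=list)  # (gene, variant id, effect)
    founder_haplotypes: list | None = None  # only when record_founders is set

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=float)


# ---------------------------------------------------------------------------
# Haplotype simulation
# ---------------------------------------------------------------------------

def _make_gametes(haps, parent_idx, rng, positions, length, rate):
    """One recombinant gamete per requested parent (Poisson crossovers)."""
    k = parent_idx.size
    start = rng.integers(0, 2, size=k)
    gam = haps[2 * parent_idx + start].copy()
    n_x = rng.poisson(rate * length, size=k)
    for g in np.flatnonzero(n_x):
        cp = np.sort(rng.uniform(0.0, length, n_x[g]))
        parity = np.searchsorted(cp, positions) % 2
        sel = start[g] ^ parity
        p = parent_idx[g]
        gam[g] = np.where(sel == 0, haps[2 * p], haps[2 * p + 1])
    return gam


def _next_generation(blocks, rng, metas, rate, s, core_idx, n_offspring):
    """One WF generation over unlinked chromosome blocks (shared parents).

    ``blocks`` are haplotype arrays (2N × m_b); ``metas`` are (positions,
    length) pairs per block.  Selection acts on the core genotype in block 0.
    """
    n = blocks[0].shape[0] // 2
    if s > 0:
        geno = blocks[0][0::2, core_idx].astype(float) + blocks[0][1::2, core_idx]
        w = 1.0 + s * geno
        prob = w / w.sum()
    else:
        prob = None
    p1 = rng.choice(n, size=n_offspring, p=prob)
    p2 = rng.choice(n, size=n_offspring, p=prob)
    out = []
    for haps, (positions, length) in zip(blocks, metas):
        g1 = _make_gametes(haps, p1, rng, positions, length, rate)
        g2 = _make_gametes(haps, p2, rng, positions, length, rate)
        new = np.empty((2 * n_offspring, haps.shape[1]), dtype=np.int8)
        new[0::2] = g1
        new[1::2] = g2
        out.append(new)
    return out


def simulate_haplotypes(config: SimConfig, rng=None):
    """Forward Wright–Fisher simulation of the multibreed phased panel.

    Two unlinked chromosomes are transmitted through one pedigree: the focal
    region (carrying the swept core and the QTL) and, when
    ``n_background_snps > 0``, a neutral background chromosome that informs
    the genomic relationship matrix, the genotype PCs and the polygenic trait
    background — playing the role the rest of the genome plays in a real
    study.  Returns ``(HaplotypePanel, SimTruth)``.  Raises
    :class:`SweepLostError` when selection is on but the core allele is lost
    (advising a larger initial frequency).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    metas = []
    block_freqs = []
    chrom_labels = []
    for chrom, m, length in (
        (config.chrom, config.n_snps, config.region_length),
        (config.background_chrom, config.n_background_snps, config.background_length),
    ):
        if m == 0:
            continue
        positions = np.sort(rng.choice(np.arange(1, length + 1), size=m, replace=False))
        freqs = np.clip(
            rng.beta(config.founder_freq_beta, config.founder_freq_beta, m), 0.02, 0.98
        )
        metas.append((positions, length))
        block_freqs.append(freqs)
        chrom_labels.append(chrom)
    block_freqs[0][config.core_index] = config.sweep_initial_freq

    n_total = config.n_breeds * config.n_per_breed
    blocks = [
        (rng.random((2 * n_total, f.size)) < f).astype(np.int8) for f in block_freqs
    ]
    founders = np.hstack(blocks).copy() if config.record_founders else None

    trajectory = [float(blocks[0][:, config.core_index].mean())]

    # ancestral phase (neutral)
    for _ in range(config.pre_split_generations):
        blocks = _next_generation(blocks, rng, metas, config.recomb_rate, 0.0,
                                  config.core_index, n_total)
        trajectory.append(float(blocks[0][:, config.core_index].mean()))

    # split into breeds
    order = rng.permutation(n_total)
    breed_blocks = []
    for b in range(config.n_breeds):
        idx = order[b * config.n_per_breed:(b + 1) * config.n_per_breed]
        rows = np.empty(2 * idx.size, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        breed_blocks.append([blk[rows].copy() for blk in blocks])

    neutral_gens = config.post_split_generations - config.sweep_generations
    for gen in range(config.post_split_generations):
        s = config.selection_coeff if gen >= neutral_gens else 0.0
        new = []
        for pop in breed_blocks:
            s_pop = s if pop[0][:, config.core_index].any() else 0.0
            new.append(_next_generation(pop, rng, metas, config.recomb_rate, s_pop,
                                        config.core_index, config.n_per_breed))
        breed_blocks = new
        trajectory.append(float(np.mean(
            [pop[0][:, config.core_index].mean() for pop in breed_blocks]
        )))

    if config.selection_coeff > 0 and trajectory[-1] == 0.0:
        raise SweepLostError(
            "selected allele lost during the sweep; increase sweep_initial_freq "
            "or the population size"
        )

    # crossbreds: inter-breed matings in the final generation
    n_pure = config.n_breeds * config.n_per_breed
    n_cross = int(round(config.crossbred_fraction * n_pure
                        / (1 - config.crossbred_fraction)))
    cross_blocks = [np.empty((2 * n_cross, f.size), dtype=np.int8) for f in block_freqs]
    for i in range(n_cross):
        ba, bb = rng.choice(config.n_breeds, size=2, replace=False)
        pa = np.array([rng.integers(config.n_per_breed)])
        pb = np.array([rng.integers(config.n_per_breed)])
        for k, meta in enumerate(metas):
            cross_blocks[k][2 * i] = _make_gametes(
                breed_blocks[ba][k], pa, rng, meta[0], meta[1], config.recomb_rate)[0]
            cross_blocks[k][2 * i + 1] = _make_gametes(
                breed_blocks[bb][k], pb, rng, meta[0], meta[1], config.recomb_rate)[0]

    all_blocks = [
        np.vstack([pop[k] for pop in breed_blocks] + [cross_blocks[k]])
        for k in range(len(metas))
    ]
    all_haps = np.hstack(all_blocks)

    samples, breed_of = [], {}
    for b in range(config.n_breeds):
        for i in range(config.n_per_breed):
            name = f"breed{b + 1}_{i + 1:04d}"
            samples.append(name)
            breed_of[name] = f"breed{b + 1}"
    for i in range(n_cross):
        name = f"cross_{i + 1:04d}"
        samples.append(name)
        breed_of[name] = "crossbred"

    chroms, positions_all = [], []
    for chrom, (positions, _) in zip(chrom_labels, metas):
        chroms.extend([chrom] * positions.size)
        positions_all.append(positions)
    positions_all = np.concatenate(positions_all)
    m_all = positions_all.size
    refs = np.where(rng.random(m_all) < 0.5, "A", "C")
    alts = np.where(refs == "A", "G", "T")
    variants = make_variant_table(chroms, positions_all, refs, alts)
    panel = HaplotypePanel(variants, samples, all_haps)

    truth = SimTruth(
        core_id=str(variants["id"].iloc[config.core_index]),
        sweep_trajectory=trajectory,
        final_core_freq=float(all_haps[:, config.core_index].mean()),
        breed_of_sample=breed_of,
        founder_haplotypes=founders.tolist() if founders is not None else None,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(panel: HaplotypePanel, config: SimConfig,
                        truth: SimTruth | None = None, rng=None) -> pd.DataFrame:
    """Four trait liabilities on the simulated panel.

    liability = QTL dosage × effect + polygenic term (scaled to h²)
    + contemporary-group effect + correlated residual (variance 1 − h²).
    Puberty is emitted as 0/1 by thresholding its liability at the empirical
    quantile matching the configured prevalence; the other traits stay on
    the continuous liability scale.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if truth is None:
        truth = SimTruth()
    geno = panel.to_genotypes()
    n = geno.n
    qtl_idx = config.core_index if config.qtl_index is None else config.qtl_index
    effects = np.asarray(config.qtl_effects, dtype=float)
    if config.mediated:
        # trait effects proportional to the variant's expression effect
        effects = effects * config.eqtl_effect
    x_qtl = geno.dosage[:, qtl_idx].astype(float)

    k = len(TRAITS)
    liab = np.zeros((n, k))
    liab += x_qtl[:, None] * effects[None, :]

    # polygenic background: many small independent effects per trait, drawn
    # from the background chromosome when present (the focal region stands
    # for one locus of a much larger genome)
    chrom_col = geno.variants["chrom"].astype(str).to_numpy()
    pool = np.flatnonzero(chrom_col == str(config.background_chrom))
    if pool.size == 0:
        pool = np.arange(geno.m)
    poly_idx = rng.choice(pool, size=min(config.n_polygenic, pool.size), replace=False)
    z = geno.dosage[:, poly_idx].astype(float)
    z = z - z.mean(axis=0)
    realized_h2 = {}
    for j, trait in enumerate(TRAITS):
        u = rng.normal(size=poly_idx.size)
        g = z @ u
        sd = g.std()
        h2 = config.h2[j]
        if sd > 0 and h2 > 0:
            g = g / sd * np.sqrt(h2)
        else:
            g = np.zeros(n)
        liab[:, j] += g
        realized_h2[trait] = float(h2)

    # correlated residuals with variance 1 − h² per trait
    r = np.asarray(config.residual_cor, dtype=float)
    chol = np.linalg.cholesky(r)
    e = rng.normal(size=(n, k)) @ chol.T
    e *= np.sqrt(1.0 - np.asarray(config.h2))[None, :]
    liab += e

    groups = rng.integers(config.n_groups, size=n)
    group_eff = rng.normal(scale=config.group_effect_sd, size=config.n_groups)
    liab += group_eff[groups][:, None]

    pheno = pd.DataFrame({"sample": list(panel.samples)})
    pheno["group"] = [f"grp{g + 1}" for g in groups]
    for j, trait in enumerate(TRAITS):
        pheno[trait] = liab[:, j]
    thresh = float(np.quantile(liab[:, 3], 1.0 - config.puberty_prevalence))
    pheno["puberty"] = (liab[:, 3] > thresh).astype(float)

    truth.qtl_id = str(geno.variants["id"].iloc[qtl_idx])
    truth.qtl_effects = {tr: float(b) for tr, b in zip(TRAITS, effects)}
    truth.realized_h2 = realized_h2
    truth.puberty_threshold = thresh
    truth.realized_prevalence = float(pheno["puberty"].mean())
    return pheno


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(panel: HaplotypePanel, config: SimConfig,
                        truth: SimTruth | None = None, rng=None):
    """Cis expression with planted eQTL(s) and its marginal summary statistics.

    Returns ``(expression_vector, eqtl_table)``; the table follows the eQTL
    column contract (gene, gene_start, chrom, pos, ref, alt, beta, se, p)
    plus freq/n/id columns so it can feed the conditional machinery
    directly.  Supports a second independent eQTL for the two-signal
    conditional analysis.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if truth is None:
        truth = SimTruth()
    geno = panel.to_genotypes()

    def _segregating(idx):
        """Snap a planted index to the nearest variant with MAF >= 0.05 on the
        same chromosome (drift can have fixed the originally chosen site)."""
        freq = geno.allele_freq()
        maf = np.minimum(freq, 1 - freq)
        chroms = geno.variants["chrom"].astype(str).to_numpy()
        ok = np.flatnonzero((maf >= 0.05) & (chroms == chroms[idx]))
        if ok.size == 0:
            raise ValueError("no segregating variant available for the eQTL")
        return int(ok[np.argmin(np.abs(ok - idx))])

    e_idx = config.core_index if config.eqtl_index is None else config.eqtl_index
    e_idx = _segregating(e_idx)
    gene_start = (
        int(geno.variants["pos"].iloc[config.core_index])
        if config.gene_start is None
        else config.gene_start
    )
    expr = config.eqtl_effect * geno.dosage[:, e_idx].astype(float)
    planted = [(config.gene_name, str(geno.variants["id"].iloc[e_idx]),
                float(config.eqtl_effect))]
    if config.second_eqtl_index is not None:
        idx2 = _segregating(config.second_eqtl_index)
        expr = expr + config.second_eqtl_effect * geno.dosage[:, idx2]
        planted.append(
            (config.gene_name,
             str(geno.variants["id"].iloc[idx2]),
             float(config.second_eqtl_effect))
        )
    expr = expr + rng.normal(scale=config.expression_noise_sd, size=geno.n)

    stats = marginal_ols_scan(expr, geno)
    stats.insert(0, "gene", config.gene_name)
    stats.insert(1, "gene_start", gene_start)
    # keep only cis variants: focal chromosome, within 2 Mb of the gene start
    cis = (stats["chrom"].astype(str) == str(config.chrom)) & (
        np.abs(stats["pos"] - gene_start) <= 2_000_000
    )
    stats = stats[cis].reset_index(drop=True)

    truth.eqtl_truth = planted
    return expr, stats


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig):
    """Run the three simulators with one root seed; returns (panel, pheno, eqtl, truth)."""
    rng = np.random.default_rng(config.seed)
    panel, truth = simulate_haplotypes(config, rng)
    pheno = simulate_phenotypes(panel, config, truth, rng)
    _, eqtl = simulate_expression(panel, config, truth, rng)
    return panel, pheno, eqtl, truth


def write_fixture_bundle(config: SimConfig, outdir) -> dict:
    """Write VCF + phenotype TSV + eQTL TSV + truth JSON; byte-deterministic under seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, pheno, eqtl, truth = simulate_bundle(config)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(panel, paths["vcf"])
    write_phenotypes(pheno, paths["phenotypes"])
    eqtl.to_csv(paths["eqtl"], sep="\t", index=False, float_format="%.12g")
    paths["truth"].write_text(truth.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
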