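import numpy as np
import pytest

from pleiosweep.genio import GenotypeMatrix, HaplotypePanel, make_variant_table
from pleiosweep.gwas_lmm import (
    build_covariates,
    compute_grm,
    compute_heterozygosity,
    compute_pcs,
    mlma_scan,
)
from pleiosweep.cojo import LdReference
from pleiosweep.mgwas import align_traits, estimate_t_correlation
from pleiosweep.synthetic_data import TRAITS, SimConfig, simulate_bundle


def make_geno(dosage, chrom="1", pos=None, samples=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    variants = make_variant_table([chrom] * m, pos, ["A"] * m, ["G"] * m)
    return GenotypeMatrix(variants, samples, dosage)


def make_panel(haplotypes, chrom="1", pos=None) -> HaplotypePanel:
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n2, m = haplotypes.shape
    assert n2 % 2 == 0
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    variants = make_variant_table([chrom] * m, pos, ["A"] * m, ["G"] * m)
    return HaplotypePanel(variants, [f"s{i}" for i in range(n2 // 2)], haplotypes)


def random_geno(rng, n, m, freq_low=0.1, freq_high=0.9) -> GenotypeMatrix:
    f = rng.uniform(freq_low, freq_high, m)
    return make_geno(rng.binomial(2, f, size=(n, m)).astype(float))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic replicate with all pipeline products."""
    cfg = SimConfig(seed=1)
    panel, pheno, eqtl, truth = simulate_bundle(cfg)
    from pleiosweep.genio import maf_filter

    geno = maf_filter(panel.to_genotypes(), 0.0005)
    covar = build_covariates(
        groups=pheno["group"],
        heterozygosity=compute_heterozygosity(geno),
        pcs=compute_pcs(geno),
        n=geno.n,
    )
    grm = compute_grm(geno)
    from pleiosweep.gwas_lmm import reml_fit, whitened_reference

    scans, refs = {}, {}
    for tr in TRAITS:
        y = pheno[tr].to_numpy(float)
        vc = reml_fit(y, covar, grm)
        scans[tr] = mlma_scan(y, covar, grm, geno, vc=vc)
        refs[tr] = LdReference(whitened_reference(y, covar, grm, geno, vc=vc), center=False)
    tmat = align_traits(scans, list(TRAITS))
    estimate_t_correlation(tmat)
    return {
        "config": cfg,
        "panel": panel,
        "pheno": pheno,
        "eqtl": eqtl,
        "truth": truth,
        "geno": geno,
        "covar": covar,
        "grm": grm,
        "scans": scans,
        "tmat": tmat,
        "ld": LdReference(geno),
        "refs": refs,
    }
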