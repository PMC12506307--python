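"""Genotype, haplotype, phenotype and summary-statistic I/O.

All pipeline stages exchange a small set of containers defined here:

* :class:`GenotypeMatrix` — samples × variants alt-allele dosage (0/1/2),
* :class:`HaplotypePanel` — phased binary haplotypes (two rows per sample),
* summary-statistic tables — plain :class:`pandas.DataFrame` objects with the
  column contract ``chrom, pos, ref, alt, beta, se, p, freq, n`` (trait GWAS)
  or ``gene, gene_start, chrom, pos, ref, alt, beta, se, p`` (cis-eQTL).

Coordinates are 1-based inclusive in files (VCF convention) and in the
``pos`` columns; array indices are 0-based internally.  Dosage always counts
copies of the *alt* allele, and every effect size in the package refers to
the alt allele.  Missing genotypes and multi-allelic records are rejected:
the pipeline consumes imputed, phased, biallelic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

SUMSTATS_COLUMNS = ["chrom", "pos", "ref", "alt", "beta", "se", "p", "freq", "n"]

EQTL_COLUMNS = ["gene", "gene_start", "chrom", "pos", "ref", "alt", "beta", "se", "p"]

#: cis window half-width around the gene start (bp).
CIS_WINDOW_BP = 2_000_000


def default_variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def make_variant_table(chrom, pos, ref, alt, ids=None) -> pd.DataFrame:
    """Assemble and validate a variant table (the VariantIndex of the pipeline)."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    if ids is None:
        ids = [default_variant_id(c, p, r, a) for c, p, r, a in zip(chrom, pos, ref, alt)]
    table = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": list(ids), "ref": ref, "alt": alt}
    )
    validate_variant_table(table)
    return table


def validate_variant_table(variants: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    for col in ("ref", "alt"):
        if (variants[col].astype(str).str.len() == 0).any():
            raise ValueError("empty allele string in variant table")
    same = variants["ref"].astype(str) == variants["alt"].astype(str)
    if same.any():
        i = int(np.flatnonzero(same.to_numpy())[0])
        raise ValueError(f"ref == alt at row {i} ({variants['id'].iloc[i]})")
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            j = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise ValueError(
                f"unsorted variants on {chrom}: pos {pos[j + 1]} follows {pos[j]}"
            )


@dataclass
class GenotypeMatrix:
    """Hard-called alt-allele dosages for n samples × m variants."""

    variants: pd.DataFrame
    samples: list
    dosage: np.ndarray  # (n, m), values in {0, 1, 2}

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples × {len(self.variants)} variants"
            )
        validate_variant_table(self.variants)

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def m(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Observed alt-allele frequency per variant."""
        return self.dosage.mean(axis=0) / 2.0

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.dosage[:, idx],
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes; rows 2*i and 2*i+1 belong to sample i."""

    variants: pd.DataFrame
    samples: list
    haplotypes: np.ndarray  # (2n, m), values in {0, 1}

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"haplotype shape {self.haplotypes.shape} inconsistent with "
                f"{len(self.samples)} samples × {len(self.variants)} variants"
            )
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        validate_variant_table(self.variants)

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def m(self) -> int:
        return len(self.variants)

    def sample_of_hap(self, hap_row: int):
        return self.samples[hap_row // 2]

    def to_genotypes(self) -> GenotypeMatrix:
        dosage = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(self.variants.copy(), list(self.samples), dosage)

    def take_variants(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.haplotypes[:, idx],
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region=None):
    """Read a phased VCF into a (HaplotypePanel, GenotypeMatrix) pair.

    Parameters
    ----------
    path : str
        Uncompressed or bgzipped VCF with phased ``GT`` fields.
    region : tuple, optional
        ``(chrom, start, end)`` with a 1-based inclusive span, or a
        ``"chrom:start-end"`` string.  Filtering is done in stream (no index
        required).

    Multi-allelic records, missing genotypes and unphased genotypes are
    rejected with an error naming the first offending record; imputation and
    record splitting are out of scope for this pipeline.
    """
    from cyvcf2 import VCF

    if isinstance(region, str):
        chrom, span = region.split(":")
        start, end = (int(x.replace(",", "")) for x in span.split("-"))
        region = (chrom, start, end)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts, ids = [], [], [], [], []
    hap_cols = []
    last = {}
    for rec in vcf:
        if region is not None:
            c, s, e = region
            if str(rec.CHROM) != str(c) or not (s <= rec.POS <= e):
                continue
        name = f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {name}; split or drop it first")
        prev = last.get(rec.CHROM)
        if prev is not None and rec.POS <= prev:
            raise ValueError(
                f"unsorted VCF: {name} follows position {prev} on {rec.CHROM}"
            )
        last[rec.CHROM] = rec.POS
        gts = rec.genotypes  # per sample: [allele0, allele1, phased]
        col = np.empty((2, len(samples)), dtype=np.int8)
        for j, g in enumerate(gts):
            if len(g) < 3:
                raise ValueError(f"non-diploid genotype at {name}, sample {samples[j]}")
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype at {name}, sample {samples[j]} "
                    "(imputed input required)"
                )
            if not phased:
                raise ValueError(f"unphased genotype at {name}, sample {samples[j]}")
            col[0, j] = a0
            col[1, j] = a1
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ids.append(
            rec.ID if rec.ID not in (None, ".") else default_variant_id(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        )
        hap_cols.append(col)
    vcf.close()

    if hap_cols:
        haps = np.empty((2 * len(samples), len(hap_cols)), dtype=np.int8)
        for k, col in enumerate(hap_cols):
            haps[0::2, k] = col[0]
            haps[1::2, k] = col[1]
    else:
        haps = np.zeros((2 * len(samples), 0), dtype=np.int8)
    variants = make_variant_table(chroms, positions, refs, alts, ids)
    panel = HaplotypePanel(variants, samples, haps)
    return panel, panel.to_genotypes()


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write a HaplotypePanel as a minimal phased VCF 4.2 (round-trips with read_vcf)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.samples)
            + "\n"
        )
        h = panel.haplotypes
        for k, row in enumerate(panel.variants.itertuples(index=False)):
            gts = "\t".join(
                f"{h[2 * i, k]}|{h[2 * i + 1, k]}" for i in range(panel.n)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Summary-statistic tables
# ---------------------------------------------------------------------------

def validate_sumstats(stats: pd.DataFrame) -> None:
    """Check the summary-statistic column contract and value ranges."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    se = stats["se"].to_numpy(dtype=float)
    p = stats["p"].to_numpy(dtype=float)
    freq = stats["freq"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(se > 0))
    if bad.size:
        raise ValueError(f"se <= 0 at row {int(bad[0]) + 1}")
    bad = np.flatnonzero(~((p > 0) & (p <= 1)))
    if bad.size:
        raise ValueError(f"p outside (0, 1] at row {int(bad[0]) + 1}")
    bad = np.flatnonzero(~((freq > 0) & (freq < 1)))
    if bad.size:
        raise ValueError(f"freq outside (0, 1) at row {int(bad[0]) + 1}")


def read_sumstats(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    validate_sumstats(stats)
    return stats


def write_sumstats(stats: pd.DataFrame, path) -> None:
    validate_sumstats(stats)
    stats.to_csv(path, sep="\t", index=False, float_format="%.12g")


def validate_eqtl_table(table: pd.DataFrame) -> None:
    missing = [c for c in EQTL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"eQTL table missing columns: {missing}")
    se = table["se"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(se > 0))
    if bad.size:
        raise ValueError(f"se <= 0 at row {int(bad[0]) + 1}")
    dist = np.abs(table["pos"].to_numpy(np.int64) - table["gene_start"].to_numpy(np.int64))
    bad = np.flatnonzero(dist > CIS_WINDOW_BP)
    if bad.size:
        raise ValueError(
            f"non-cis row {int(bad[0]) + 1}: variant {int(dist[bad[0]])} bp from gene start "
            f"(limit {CIS_WINDOW_BP})"
        )


def read_eqtl_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    validate_eqtl_table(table)
    return table


def write_eqtl_table(table: pd.DataFrame, path) -> None:
    validate_eqtl_table(table)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def maf_filter(geno: GenotypeMatrix, threshold: float = 0.0005) -> GenotypeMatrix:
    """Drop variants with minor allele frequency <= threshold (strict MAF > t)."""
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    freq = geno.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(maf > threshold)
    return geno.take_variants(keep)
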