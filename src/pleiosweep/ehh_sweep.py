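"""Extended haplotype homozygosity (EHH) and sweep diagnostics.

EHH at a flanking position x, for the haplotypes carrying a given core
allele, is the probability that two randomly drawn carrier haplotypes are
identical over the whole interval [core, x]:

    EHH(x) = sum_h C(n_h, 2) / C(c, 2)

with n_h the carrier count of each distinct extended haplotype and c the
carrier total.  A recent positive sweep drags long shared haplotypes to high
frequency around the selected allele, so its EHH decays more slowly; the
area under the EHH curve against physical distance (trapezoidal, both
flanks, bp units) summarises the decay in one number per allele.

The implementation sorts carrier haplotypes lexicographically outward from
the core, records where adjacent sorted haplotypes first differ, and then
sweeps the flank once while merging runs — O(c log c · L) overall — which is
verified in the tests against brute-force pair enumeration.

Also here: the permutation contrast of AUC between two loci (carrier sets
pooled and re-partitioned), the Wilcoxon signed-rank comparison of paired
allele profiles, the chi-square count test over candidate QTLs, and the
two-locus genotype co-inheritance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import GenotypeMatrix, HaplotypePanel


@dataclass
class EhhProfile:
    """EHH values at every SNP position of a region around one core allele."""

    core_id: str
    core_pos: int
    allele: int
    positions: np.ndarray  # ascending, includes the core position
    ehh: np.ndarray  # aligned with positions; 1.0 at the core
    carriers: int


@dataclass
class AucResult:
    auc: float  # bp
    allele: int
    start: int
    end: int


def _flank_ehh(h: np.ndarray) -> np.ndarray:
    """EHH per prefix length of a carrier submatrix with column 0 at the core.

    Returns ehh[j] = fraction of carrier pairs identical over columns 0..j.
    """
    c, length = h.shape
    if length == 0:
        return np.zeros(0)
    if c < 2:
        raise ValueError("insufficient carriers")
    h = np.ascontiguousarray(h, dtype=np.int8)
    rows = h.view(np.dtype((np.void, length)))[:, 0]
    order = np.argsort(rows, kind="stable")  # byte-wise == lexicographic for 0/1
    hs = h[order]
    neq = hs[1:] != hs[:-1]
    has_diff = neq.any(axis=1)
    d = np.where(has_diff, neq.argmax(axis=1), length)  # first differing column

    total_pairs = c * (c - 1) // 2
    ehh = np.empty(length)
    # Walk j downward merging adjacent runs as breaks (d_i <= j) disappear.
    start_of = np.arange(c)
    end_of = np.arange(c)
    merge_order = np.argsort(d, kind="stable")[::-1]
    pairs = 0
    ptr = 0
    n_breaks = c - 1
    for j in range(length - 1, -1, -1):
        while ptr < n_breaks and d[merge_order[ptr]] > j:
            i = int(merge_order[ptr])
            a = start_of[i]
            b = end_of[i + 1]
            pairs += (i - a + 1) * (b - i)
            end_of[a] = b
            start_of[b] = a
            ptr += 1
        ehh[j] = pairs / total_pairs
    return ehh


def _core_index(panel: HaplotypePanel, core_variant) -> int:
    if isinstance(core_variant, (int, np.integer)):
        return int(core_variant)
    idx = np.flatnonzero((panel.variants["id"] == core_variant).to_numpy())
    if idx.size == 0:
        raise KeyError(f"core variant {core_variant!r} not in panel")
    return int(idx[0])


def _profile_for_rows(panel: HaplotypePanel, core_idx: int, rows: np.ndarray,
                      core_id: str, allele: int) -> EhhProfile:
    # flanks extend over the core's chromosome only
    chroms = panel.variants["chrom"].astype(str).to_numpy()
    cols = np.flatnonzero(chroms == chroms[core_idx])
    h = panel.haplotypes[np.ix_(rows, cols)]
    pos = panel.variants["pos"].to_numpy()[cols]
    core_idx = int(np.searchsorted(cols, core_idx))
    right = _flank_ehh(h[:, core_idx:])
    left = _flank_ehh(h[:, core_idx::-1])
    ehh = np.concatenate([left[::-1], right[1:]])
    return EhhProfile(
        core_id=core_id,
        core_pos=int(pos[core_idx]),
        allele=allele,
        positions=pos.copy(),
        ehh=ehh,
        carriers=len(rows),
    )


def ehh_decay(panel: HaplotypePanel, core_variant, allele: int) -> EhhProfile:
    """EHH decay profile for one core allele, out to both panel edges.

    Requires at least two carrier haplotypes; no early-termination cutoff is
    applied (profiles are integrated over the full extracted region).
    """
    core_idx = _core_index(panel, core_variant)
    carriers = np.flatnonzero(panel.haplotypes[:, core_idx] == allele)
    if carriers.size < 2:
        raise ValueError(
            f"insufficient carriers of allele {allele} at "
            f"{panel.variants['id'].iloc[core_idx]} ({carriers.size})"
        )
    return _profile_for_rows(
        panel, core_idx, carriers, str(panel.variants["id"].iloc[core_idx]), allele
    )


def ehh_auc(profile: EhhProfile) -> AucResult:
    """Trapezoidal area under EHH vs physical position, both flanks, in bp."""
    left = profile.positions <= profile.core_pos
    right = profile.positions >= profile.core_pos
    auc = float(
        np.trapezoid(profile.ehh[left], profile.positions[left])
        + np.trapezoid(profile.ehh[right], profile.positions[right])
    )
    return AucResult(
        auc=auc,
        allele=profile.allele,
        start=int(profile.positions[0]),
        end=int(profile.positions[-1]),
    )


def _auc_for_rows(panel, core_idx, rows) -> float:
    prof = _profile_for_rows(panel, core_idx, rows, "perm", -1)
    return ehh_auc(prof).auc


def permutation_auc_contrast(
    panel: HaplotypePanel,
    core_a,
    allele_a: int,
    core_b,
    allele_b: int,
    n_perm: int = 10_000,
    seed=None,
) -> tuple[float, float]:
    """Permutation test of AUC(core A allele) − AUC(core B allele).

    The two carrier haplotype sets are pooled and re-partitioned at random
    into groups of the original sizes; each permutation recomputes both AUCs
    with each locus's own core.  Two-sided
    p = (#{|null| >= |obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is small; p-value resolution is coarse")
    rng = np.random.default_rng(seed)
    ia = _core_index(panel, core_a)
    ib = _core_index(panel, core_b)
    rows_a = np.flatnonzero(panel.haplotypes[:, ia] == allele_a)
    rows_b = np.flatnonzero(panel.haplotypes[:, ib] == allele_b)
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError("insufficient carriers at one of the cores")
    obs = _auc_for_rows(panel, ia, rows_a) - _auc_for_rows(panel, ib, rows_b)

    pooled = np.concatenate([rows_a, rows_b])
    na = rows_a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = _auc_for_rows(panel, ia, perm[:na]) - _auc_for_rows(panel, ib, perm[na:])
        if abs(diff) >= abs(obs):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(obs), float(p)


def wilcoxon_allele_ehh(profile_pairs) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired allele EHH values.

    ``profile_pairs`` is a list of (profile_primary, profile_other) pairs —
    e.g. (height-increasing allele, other allele) per locus — paired at
    matched SNP positions and pooled across loci.  Zero differences are
    dropped; if every pair is tied the statistic is 0 with p = 1.
    """
    diffs = []
    for a, b in profile_pairs:
        if not np.array_equal(a.positions, b.positions):
            raise ValueError("profiles in a pair must share SNP positions")
        diffs.append(a.ehh - b.ehh)
    d = np.concatenate(diffs)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    res = stats.wilcoxon(d)
    # signed statistic W+ − W−: positive when the primary allele's EHH is
    # larger; antisymmetric under swapping the alleles
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return w_plus - w_minus, float(res.pvalue)


def count_chi_square(n_with_longer: int, n_total: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square of an observed count against a 50:50 null.

    Used for "how many of the candidate QTLs show the longer extended
    haplotype on the focal allele"; df = 1.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with_longer <= n_total:
        raise ValueError("count outside [0, n_total]")
    res = stats.chisquare([n_with_longer, n_total - n_with_longer])
    return float(res.statistic), float(res.pvalue)


def co_inheritance_test(geno: GenotypeMatrix, locus_a, locus_b):
    """Pearson chi-square of independence on the 3 × 3 genotype table.

    Tests whether genotypes at two loci are co-inherited more often than
    expected by chance; df = 4 for the full table.  Genotype classes with a
    zero margin are collapsed (dropped) with a warning, reducing df.
    Returns (chi2, df, p).
    """
    lookup = geno.variants.reset_index().set_index("id")["index"]
    ia = int(lookup[locus_a]) if not isinstance(locus_a, (int, np.integer)) else int(locus_a)
    ib = int(lookup[locus_b]) if not isinstance(locus_b, (int, np.integer)) else int(locus_b)
    da = geno.dosage[:, ia].astype(int)
    db = geno.dosage[:, ib].astype(int)
    table = np.zeros((3, 3))
    for ga, gb in zip(da, db):
        table[ga, gb] += 1
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("zero-margin genotype class collapsed; df reduced")
        table = table[rows][:, cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("co-inheritance table degenerate after collapsing")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
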