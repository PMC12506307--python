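"""Multi-trait GWAS from signed t-values.

Four (or k) single-trait scans are combined per variant through the
quadratic form

    X^2 = t' V^{-1} t,

where t holds the signed t-values of one variant across traits and V is the
k × k Pearson correlation matrix of t-values estimated over all scanned
variants.  Under the null X^2 is chi-square with k degrees of freedom
(df = 4 for the four traits analysed here).  The approach needs only effect
estimates per marker, not phenotypes recorded on common individuals, but it
does require every marker to carry an estimate for every trait — variants
missing from any scan are dropped during alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MGWAS_ALPHA = 1e-9  # genome-wide threshold, 0.05 / ~4.47e7 tests to 1 s.f.
EIGEN_FLOOR = 1e-6


@dataclass
class TMatrix:
    """Aligned signed t-values (m variants × k traits) and their correlation."""

    variants: pd.DataFrame  # chrom, pos, id, ref, alt (+ freq of the common alt)
    traits: list
    t: np.ndarray  # (m, k)
    v: np.ndarray | None = None  # (k, k) t-value correlation
    n_dropped: int = 0

    @property
    def k(self) -> int:
        return len(self.traits)

    @property
    def m(self) -> int:
        return self.t.shape[0]


def _keyed(scan: pd.DataFrame) -> pd.DataFrame:
    out = scan.copy()
    out["_key"] = (
        out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    )
    return out


def align_traits(scans: dict | list, traits: list | None = None) -> TMatrix:
    """Intersect variant sets across single-trait scans and harmonise alleles.

    Effects are flipped to a common alt allele (the first scan's): when a
    scan's ref/alt are swapped relative to it, that scan's t-value and beta
    change sign and its frequency becomes 1 − freq.  Variants absent from any
    scan, or with irreconcilable alleles, are dropped and counted.
    """
    if isinstance(scans, dict):
        traits = list(scans.keys()) if traits is None else traits
        scans = [scans[tr] for tr in traits]
    else:
        scans = list(scans)
        if traits is None:
            traits = [f"trait{i + 1}" for i in range(len(scans))]
    if len(scans) < 2:
        raise ValueError("need at least two scans to align")

    keyed = [_keyed(s) for s in scans]
    base = keyed[0].set_index("_key")
    common = base.index
    for s in keyed[1:]:
        common = common.intersection(s.set_index("_key").index)
    total = len(base)
    if len(common) == 0:
        raise ValueError("no variants shared by all scans")

    ref = base.loc[common]
    tcols = []
    keep = np.ones(len(common), dtype=bool)
    for s in keyed:
        sub = s.set_index("_key").loc[common]
        t = (sub["beta"] / sub["se"]).to_numpy(dtype=float)
        swapped = (sub["ref"].to_numpy() == ref["alt"].to_numpy()) & (
            sub["alt"].to_numpy() == ref["ref"].to_numpy()
        )
        matched = (sub["ref"].to_numpy() == ref["ref"].to_numpy()) & (
            sub["alt"].to_numpy() == ref["alt"].to_numpy()
        )
        t = np.where(swapped, -t, t)
        keep &= matched | swapped
        if "collinear" in sub.columns:
            keep &= ~sub["collinear"].to_numpy(dtype=bool)
        tcols.append(t)
    t = np.column_stack(tcols)[keep]
    variants = (
        ref.reset_index(drop=True)[["chrom", "pos", "id", "ref", "alt", "freq"]]
        .iloc[np.flatnonzero(keep)]
        .reset_index(drop=True)
    )
    n_dropped = total - int(keep.sum())
    return TMatrix(variants, traits, t, n_dropped=n_dropped)


def estimate_t_correlation(tmat: TMatrix, null_only: bool = False) -> np.ndarray:
    """Pearson correlation of signed t-values between each pair of traits.

    Computed over all aligned variants by default (``null_only=True``
    restricts to rows with every |t| < 2, a common sensitivity variant).
    Near-singular estimates are shrunk toward the identity just enough to
    push the smallest eigenvalue to 1e-6.
    """
    t = tmat.t
    if null_only:
        t = t[(np.abs(t) < 2).all(axis=1)]
    if t.shape[0] < tmat.k + 1:
        raise ValueError("too few variants to estimate the t-correlation")
    if np.any(t.std(axis=0) == 0):
        raise ValueError("constant t-value column; correlation undefined")
    v = np.corrcoef(t, rowvar=False)
    v = (v + v.T) / 2
    emin = np.linalg.eigvalsh(v).min()
    if emin < EIGEN_FLOOR:
        lam = (EIGEN_FLOOR - emin) / (1.0 - emin)
        v = (1 - lam) * v + lam * np.eye(v.shape[0])
    np.fill_diagonal(v, 1.0)
    tmat.v = v
    return v


def mgwas_statistic(t_row, v) -> tuple[float, float]:
    """X² = t' V⁻¹ t with an upper-tail chi-square p at df = len(t)."""
    t_row = np.asarray(t_row, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.shape != (t_row.size, t_row.size):
        raise ValueError(f"V shape {v.shape} does not match t of length {t_row.size}")
    x2 = float(t_row @ np.linalg.solve(v, t_row))
    p = float(stats.chi2.sf(x2, df=t_row.size))
    return x2, p


def mgwas_scan(tmat: TMatrix, alpha: float = MGWAS_ALPHA) -> pd.DataFrame:
    """Row-wise multi-trait statistic over an aligned TMatrix.

    Returns the variant table with ``x2`` and ``p`` columns plus a
    ``significant`` flag at the configured threshold (default 1e-9).
    """
    if tmat.v is None:
        estimate_t_correlation(tmat)
    vinv = np.linalg.inv(tmat.v)
    x2 = np.einsum("ij,jk,ik->i", tmat.t, vinv, tmat.t)
    x2 = np.maximum(x2, 0.0)
    p = stats.chi2.sf(x2, df=tmat.k)
    out = tmat.variants.copy()
    out["x2"] = x2
    out["p"] = p
    out["significant"] = p < alpha
    return out
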