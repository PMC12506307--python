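"""Conditional and joint association analysis from summary statistics.

Given marginal per-SNP effects (beta, se, p, freq, n) and an LD reference
panel, this module reconstructs the multiple-regression normal equations:
with centred genotypes, X'X = n·D·R·D and X'y_j = n·sd_j²·beta_j, where R is
the reference correlation matrix and D = diag(sd).  The phenotypic variance
is reconstructed per SNP from (beta, se, n, sd) and medianed across SNPs.

``conditional_scan`` reports, for each target SNP, its coefficient in the
joint fit of {condition set ∪ target}; when the LD reference *is* the GWAS
sample this reproduces individual-level multiple regression exactly, which
is the correctness contract the tests enforce.  Targets in strong LD with a
conditioning SNP (r² above the collinearity cap) are excluded and flagged,
mirroring how conditioned variants are pruned from downstream multi-trait
rounds.  SNP pairs farther apart than the LD window (or on different
chromosomes) are treated as unlinked (r = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix

COLLINEARITY_R2 = 0.9
LD_WINDOW_BP = 10_000_000


@dataclass
class LdReference:
    """LD reference panel: centred dosages plus per-variant mean/sd.

    ``center=False`` treats the stored values as already centred/projected
    (e.g. the whitened genotype matrix of a mixed-model scan) and uses raw
    second moments.
    """

    geno: GenotypeMatrix
    center: bool = True
    centered: np.ndarray = field(init=False)
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)

    def __post_init__(self):
        x = self.geno.dosage.astype(float)
        self.mean = x.mean(axis=0) if self.center else np.zeros(x.shape[1])
        self.centered = x - self.mean
        self.sd = np.sqrt((self.centered**2).mean(axis=0))

    @property
    def n_ref(self) -> int:
        return self.geno.n

    def index_of(self, ids) -> np.ndarray:
        lookup = pd.Index(self.geno.variants["id"])
        idx = lookup.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"variants absent from LD reference: {missing[:5]}")
        return idx

    def correlation(self, idx_a, idx_b, window_bp: int = LD_WINDOW_BP) -> np.ndarray:
        """Pearson r between two variant index sets, zeroed beyond the window."""
        idx_a = np.asarray(idx_a)
        idx_b = np.asarray(idx_b)
        za = self.centered[:, idx_a]
        zb = self.centered[:, idx_b]
        denom = np.outer(self.sd[idx_a], self.sd[idx_b]) * self.n_ref
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (za.T @ zb) / denom
        r = np.nan_to_num(r, nan=0.0)
        va = self.geno.variants
        pos_a = va["pos"].to_numpy()[idx_a]
        pos_b = va["pos"].to_numpy()[idx_b]
        chr_a = va["chrom"].to_numpy()[idx_a]
        chr_b = va["chrom"].to_numpy()[idx_b]
        far = (np.abs(pos_a[:, None] - pos_b[None, :]) > window_bp) | (
            chr_a[:, None] != chr_b[None, :]
        )
        r = np.where(far, 0.0, r)
        return r


@dataclass
class ConditionSet:
    """Ordered putative-causal variants with their joint effect estimates."""

    ids: list
    beta_joint: np.ndarray
    se_joint: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)


def _median_var_y(stats_df: pd.DataFrame, ld: LdReference) -> float:
    """Phenotypic variance reconstructed per SNP and medianed.

    From a marginal regression with intercept: RSS_j = se_j²·(n−2)·n·var_j and
    var(y) = RSS_j/n + beta_j²·var_j.
    """
    idx = ld.index_of(stats_df["id"])
    var_x = ld.sd[idx] ** 2
    n = stats_df["n"].to_numpy(dtype=float)
    se = stats_df["se"].to_numpy(dtype=float)
    beta = stats_df["beta"].to_numpy(dtype=float)
    ok = var_x > 0
    var_y = se[ok] ** 2 * (n[ok] - 2) * var_x[ok] + beta[ok] ** 2 * var_x[ok]
    if var_y.size == 0:
        raise ValueError("no polymorphic SNPs to reconstruct the phenotypic variance")
    return float(np.median(var_y))


def _check_condition_block(r_ss: np.ndarray, ids, collinearity_r2: float) -> None:
    k = r_ss.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            if r_ss[i, j] ** 2 > collinearity_r2:
                raise ValueError(
                    f"conditioning SNPs {ids[i]} and {ids[j]} are collinear "
                    f"(r² = {r_ss[i, j] ** 2:.3f})"
                )
    if np.linalg.cond(r_ss) > 1e10:
        raise ValueError("singular conditioning LD block")


def conditional_scan(
    stats_df: pd.DataFrame,
    condition_set,
    ld_ref: LdReference,
    collinearity_r2: float = COLLINEARITY_R2,
    ld_window_bp: int = LD_WINDOW_BP,
) -> pd.DataFrame:
    """Per-SNP effects conditional on the joint fit of a conditioning set.

    Returns a copy of ``stats_df`` with beta/se/p/t replaced by conditional
    values and an ``excluded`` flag for targets with r² above the
    collinearity cap against any conditioning SNP (their estimates are NaN).
    Conditioning on an empty set is the identity.
    """
    cond_ids = [c for c in condition_set]
    out = stats_df.copy().reset_index(drop=True)
    if "t" not in out.columns:
        out["t"] = out["beta"] / out["se"]
    if not cond_ids:
        out["excluded"] = False
        return out

    cond_rows = out.set_index("id")
    missing = [c for c in cond_ids if c not in cond_rows.index]
    if missing:
        raise KeyError(f"conditioning SNPs absent from summary stats: {missing}")

    idx_s = ld_ref.index_of(cond_ids)
    # targets absent from the reference cannot be conditioned: flag them
    lookup = pd.Index(ld_ref.geno.variants["id"])
    idx_t_raw = lookup.get_indexer(pd.Index(out["id"]))
    absent = idx_t_raw < 0
    idx_t = np.where(absent, 0, idx_t_raw)
    r_ss = ld_ref.correlation(idx_s, idx_s, ld_window_bp)
    _check_condition_block(r_ss, cond_ids, collinearity_r2)
    r_ts = ld_ref.correlation(idx_t, idx_s, ld_window_bp)  # (m, |S|)

    var_y = _median_var_y(out[~absent], ld_ref)
    sd_s = ld_ref.sd[idx_s]
    sd_t = ld_ref.sd[idx_t]
    beta_s = cond_rows.loc[cond_ids, "beta"].to_numpy(dtype=float)
    q_s = sd_s * beta_s  # X'y on the unit-variance scale, / n
    q_t = sd_t * out["beta"].to_numpy(dtype=float)

    m_inv = np.linalg.inv(r_ss)
    u = m_inv @ q_s
    mu_r = r_ts @ m_inv  # (m, |S|)
    g = np.einsum("ij,ij->i", mu_r, r_ts)  # r' R^-1 r per target
    h = r_ts @ u  # r' R^-1 q_S per target

    n_eff = min(
        int(out["n"].min()),
        int(cond_rows.loc[cond_ids, "n"].min()),
    )
    p_model = len(cond_ids) + 1
    df = n_eff - p_model - 1
    if df <= 0:
        raise ValueError("too few observations for the conditional model")

    excluded = (r_ts**2 > collinearity_r2).any(axis=1) | (g >= 1 - 1e-10)
    excluded |= out["id"].isin(cond_ids).to_numpy()
    excluded |= absent

    denom = np.where(excluded, 1.0, 1.0 - g)
    b_std = (q_t - h) / denom
    fit = (u @ q_s) + (q_t - h) ** 2 / denom
    rss_over_n = np.maximum(var_y - fit, 0.0)
    sigma2 = rss_over_n * n_eff / df
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_c = b_std / sd_t
        se_c = np.sqrt(sigma2 / (n_eff * denom)) / sd_t
    bad = excluded | ~np.isfinite(beta_c) | ~np.isfinite(se_c) | (se_c <= 0)
    beta_c = np.where(bad, np.nan, beta_c)
    se_c = np.where(bad, np.nan, se_c)
    with np.errstate(invalid="ignore"):
        t_c = beta_c / se_c
    p_c = 2.0 * stats.norm.sf(np.abs(t_c))
    p_c = np.clip(p_c, np.finfo(float).tiny, 1.0)

    out["beta"] = beta_c
    out["se"] = se_c
    out["t"] = t_c
    out["p"] = np.where(bad, np.nan, p_c)
    out["excluded"] = bad
    return out


def marginal_ols_scan(y, geno: GenotypeMatrix) -> pd.DataFrame:
    """Marginal per-variant OLS (intercept + SNP) summary statistics.

    This is the generative convention the conditional machinery above
    inverts: beta = cov(x, y)/var(x), se² = [RSS/(n−2)] / Σ(x−x̄)².  Used for
    eQTL-style scans and as the summary-stat source in oracle tests.
    Monomorphic variants get se = +inf, p = 1.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = geno.dosage.astype(float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    ssx = (xc**2).sum(axis=0)
    ok = ssx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, (xc * yc[:, None]).sum(axis=0) / ssx, 0.0)
    rss = (yc**2).sum() - beta**2 * ssx
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(ok, np.sqrt(np.maximum(rss, 0.0) / (n - 2) / ssx), np.inf)
        t = np.where(ok, beta / se, 0.0)
    p = np.where(ok, 2.0 * stats.norm.sf(np.abs(t)), 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = geno.variants[["chrom", "pos", "id", "ref", "alt"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["freq"] = geno.allele_freq()
    out["n"] = n
    out["t"] = t
    return out


def joint_fit(
    stats_df: pd.DataFrame,
    snp_ids,
    ld_ref: LdReference,
    collinearity_r2: float = COLLINEARITY_R2,
    ld_window_bp: int = LD_WINDOW_BP,
) -> ConditionSet:
    """Joint effect estimates for the named SNPs from marginal statistics.

    With a single SNP the joint estimate equals the marginal one; a singular
    LD block (e.g. two SNPs in perfect LD) raises, naming the collinear pair.
    """
    snp_ids = list(snp_ids)
    if len(snp_ids) < 1:
        raise ValueError("joint_fit needs at least one SNP")
    rows = stats_df.set_index("id")
    missing = [s for s in snp_ids if s not in rows.index]
    if missing:
        raise KeyError(f"SNPs absent from summary stats: {missing}")
    idx = ld_ref.index_of(snp_ids)
    r = ld_ref.correlation(idx, idx, ld_window_bp)
    _check_condition_block(r, snp_ids, collinearity_r2)

    sd = ld_ref.sd[idx]
    beta = rows.loc[snp_ids, "beta"].to_numpy(dtype=float)
    q = sd * beta
    r_inv = np.linalg.inv(r)
    b_std = r_inv @ q
    beta_joint = b_std / sd

    var_y = _median_var_y(stats_df, ld_ref)
    n_eff = int(rows.loc[snp_ids, "n"].min())
    df = n_eff - len(snp_ids) - 1
    if df <= 0:
        raise ValueError("too few observations for the joint model")
    rss_over_n = max(var_y - float(b_std @ q), 0.0)
    sigma2 = rss_over_n * n_eff / df
    se_joint = np.sqrt(sigma2 * np.diag(r_inv) / n_eff) / sd
    return ConditionSet(snp_ids, beta_joint, se_joint)
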