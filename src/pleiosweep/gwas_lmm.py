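"""Single-trait linear mixed model GWAS.

The association model per trait is

    y = Xb + g + e,    g ~ N(0, G sigma_g^2),    e ~ N(0, I sigma_e^2)

with X holding the intercept, contemporary-group indicators, genome-wide
heterozygosity and the first four genotype principal components, and G the
genomic relationship matrix.  Variance components are estimated once by REML
on the null (no-SNP) model; every variant is then tested one at a time by
generalised least squares with the covariance held fixed (standard MLMA
practice).  A binary trait is analysed on its observed 0/1 scale with the
same linear model.

Because a single relationship matrix with an identity residual is used, the
restricted likelihood reduces after eigenrotation of G to a one-dimensional
profile over the variance ratio sigma_g^2/sigma_e^2, which is maximised
directly; this is exact for the model above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix

GRM_RIDGE = 1e-6
REML_TOL = 1e-8
REML_MAX_ITER = 100  # function evaluations allowed to the scalar optimiser


@dataclass
class GRM:
    """Genomic relationship matrix (VanRaden form) with its sample ids."""

    matrix: np.ndarray
    samples: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.samples)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape inconsistent with sample list")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)).

    Frequencies are the observed alt-allele frequencies; monomorphic variants
    carry no relationship information and are skipped (m reduced accordingly).
    """
    freq = geno.allele_freq()
    poly = (freq > 0) & (freq < 1)
    if poly.sum() < 1:
        raise ValueError("all variants monomorphic; GRM undefined")
    x = geno.dosage[:, poly].astype(float)
    p = freq[poly]
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    g = (z @ z.T) / z.shape[1]
    g = (g + g.T) / 2  # enforce exact symmetry
    return GRM(g, list(geno.samples))


def compute_heterozygosity(geno: GenotypeMatrix) -> np.ndarray:
    """Proportion of heterozygous loci per sample (hybrid-content covariate)."""
    if geno.m == 0:
        raise ValueError("no variants")
    return (geno.dosage == 1).mean(axis=1)


def compute_pcs(geno: GenotypeMatrix, k: int = 4) -> np.ndarray:
    """First k principal components of the column-standardised dosage matrix.

    Scores are ordered by decreasing variance explained; each column's sign is
    fixed so that its largest-magnitude score is positive.
    """
    if k >= geno.n:
        raise ValueError(f"k = {k} must be smaller than the sample count {geno.n}")
    x = geno.dosage.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def build_covariates(
    groups=None, heterozygosity=None, pcs=None, n: int | None = None
) -> np.ndarray:
    """Assemble the fixed-effect design: intercept, one-hot groups (first level
    dropped), heterozygosity, PC scores.  Singleton groups are retained."""
    cols = []
    if groups is not None:
        groups = pd.Series(list(groups), dtype="object")
        n = len(groups)
        levels = pd.unique(groups)
        for lev in levels[1:]:
            cols.append((groups == lev).to_numpy(dtype=float))
    if n is None:
        for arr in (heterozygosity, pcs):
            if arr is not None:
                n = np.asarray(arr).shape[0]
                break
    if n is None:
        raise ValueError("cannot infer sample count for covariate design")
    design = [np.ones(n)]
    design.extend(cols)
    if heterozygosity is not None:
        design.append(np.asarray(heterozygosity, dtype=float))
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        design.extend(pcs[:, j] for j in range(pcs.shape[1]))
    return np.column_stack(design)


def _grm_eigen(grm: GRM) -> tuple[np.ndarray, np.ndarray]:
    g = grm.matrix
    d, u = np.linalg.eigh(g)
    if d.min() < -GRM_RIDGE * 10:
        g = g + GRM_RIDGE * np.eye(g.shape[0])
        d, u = np.linalg.eigh(g)
        if d.min() < -1e-8:
            raise ValueError(
                f"GRM not positive semidefinite even after ridge {GRM_RIDGE:g} "
                f"(min eigenvalue {d.min():.3g})"
            )
    d = np.clip(d, 0.0, None)
    return d, u


def _restricted_nll(log_lambda, d, ystar, xstar):
    """Negative restricted log-likelihood profiled over beta and sigma_e^2."""
    lam = np.exp(log_lambda)
    n, p = xstar.shape
    w = 1.0 / (lam * d + 1.0)
    xtwx = xstar.T @ (w[:, None] * xstar)
    xtwy = xstar.T @ (w * ystar)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = ystar - xstar @ beta
    rss = float(np.sum(w * resid**2))
    if rss <= 0:
        return np.inf
    sigma_e2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    nll = 0.5 * (
        (n - p) * np.log(sigma_e2)
        + np.sum(np.log(lam * d + 1.0))
        + logdet_xtwx
        + (n - p)
    )
    return nll


def reml_fit(y, covariates, grm: GRM) -> VarianceComponents:
    """REML variance components of y = Xb + g + e via the spectral profile.

    Missing phenotype entries (NaN) are dropped together with their rows of
    the design and GRM.  Convergence tolerance on the profiled parameter is
    1e-8; a degenerate fit raises.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariates, dtype=float)
    keep = ~np.isnan(y)
    y, x = y[keep], x[keep]
    g = GRM(grm.matrix[np.ix_(keep, keep)], [s for s, k in zip(grm.samples, keep) if k])
    n, p = x.shape
    if n <= p:
        raise ValueError(f"{n} observations cannot support {p} fixed effects")
    d, u = _grm_eigen(g)
    ystar = u.T @ y
    xstar = u.T @ x

    res = optimize.minimize_scalar(
        _restricted_nll,
        bounds=(-12.0, 12.0),
        args=(d, ystar, xstar),
        method="bounded",
        options={"xatol": REML_TOL, "maxiter": REML_MAX_ITER},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"REML did not converge: {res.message}")
    # Compare against the sigma_g^2 = 0 boundary explicitly.
    candidates = [res.x, -30.0]
    nlls = [_restricted_nll(c, d, ystar, xstar) for c in candidates]
    log_lambda = candidates[int(np.argmin(nlls))]
    lam = np.exp(log_lambda)
    w = 1.0 / (lam * d + 1.0)
    beta = np.linalg.solve(xstar.T @ (w[:, None] * xstar), xstar.T @ (w * ystar))
    resid = ystar - xstar @ beta
    sigma_e2 = float(np.sum(w * resid**2) / (n - p))
    sigma_g2 = lam * sigma_e2 if lam > 1e-12 else 0.0
    return VarianceComponents(sigma_g2, sigma_e2, -float(min(nlls)))


def _whiten(y, covariates, grm: GRM, geno: GenotypeMatrix, vc=None):
    """Rotate everything into the V^(-1/2) space of the null mixed model and
    project the fixed covariates out.  Returns (y_w, snps_w, vc, keep)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariates, dtype=float)
    keep = ~np.isnan(y)
    yk, xk = y[keep], x[keep]
    gk = GRM(grm.matrix[np.ix_(keep, keep)], [s for s, k in zip(grm.samples, keep) if k])
    if vc is None:
        vc = reml_fit(yk, xk, gk)
    d, u = _grm_eigen(gk)
    lam = vc.sigma_g2 / vc.sigma_e2 if vc.sigma_e2 > 0 else 0.0
    sw = np.sqrt(1.0 / (lam * d + 1.0))

    ystar = sw * (u.T @ yk)
    xstar = sw[:, None] * (u.T @ xk)
    snps = sw[:, None] * (u.T @ geno.dosage[keep].astype(float))
    q, _ = np.linalg.qr(xstar)
    yres = ystar - q @ (q.T @ ystar)
    sres = snps - q @ (q.T @ snps)
    return yres, sres, vc, keep, x.shape[1]


def whitened_reference(y, covariates, grm: GRM, geno: GenotypeMatrix,
                       vc: VarianceComponents | None = None) -> GenotypeMatrix:
    """Genotypes carried into the mixed model's whitened space.

    Conditional/joint summary-statistic analysis of a mixed-model scan is
    exact (equals the joint GLS fit) when its LD reference is this matrix
    rather than the raw dosages, because the scan's effect estimates are OLS
    estimates in this space.
    """
    _, sres, _, keep, _ = _whiten(y, covariates, grm, geno, vc)
    return GenotypeMatrix(
        geno.variants.copy(),
        [s for s, k in zip(geno.samples, keep) if k],
        sres,
    )


def mlma_scan(
    y,
    covariates,
    grm: GRM,
    geno: GenotypeMatrix,
    vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Mixed-linear-model association scan: each variant tested one at a time.

    Variance components come from the null model (fit here if not supplied)
    and are held fixed; each SNP's effect is the GLS estimate under
    V = sigma_g^2 G + sigma_e^2 I, computed as OLS in the whitened space with
    a per-SNP residual variance on n − p − 1 degrees of freedom (p fixed
    covariates).  Returns a summary-statistic table with the standard column
    contract plus the signed t-value ``t = beta/se`` and a ``collinear`` flag
    (se = +inf, p = 1 for variants collinear with the covariates).  Two-sided
    p-values use the standard normal on t.
    """
    yres, sres, vc, keep, p_cov = _whiten(y, covariates, grm, geno, vc)
    n_obs = int(keep.sum())
    # regression through the origin in the whitened space (the fixed
    # covariates, intercept included, are already projected out there)
    ssx = np.einsum("ij,ij->j", sres, sres)
    scale = max(float(ssx.max(initial=0.0)), 1.0)
    collinear = ssx <= scale * 1e-12
    ssy = float(yres @ yres)
    df = n_obs - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(collinear, 0.0, (sres.T @ yres) / ssx)
        rss = np.maximum(ssy - beta**2 * ssx, 0.0)
        se = np.where(collinear, np.inf, np.sqrt(rss / df / ssx))
        t = np.where(collinear | (se == 0), 0.0, beta / se)
    p = np.where(collinear, 1.0, 2.0 * stats.norm.sf(np.abs(t)))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    freq = geno.dosage[keep].mean(axis=0) / 2.0
    out = geno.variants[["chrom", "pos", "id", "ref", "alt"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["freq"] = freq
    out["n"] = n_obs
    out["t"] = t
    out["collinear"] = collinear
    return out


def scan_all_traits(
    pheno: pd.DataFrame,
    traits: list,
    covariates,
    grm: GRM,
    geno: GenotypeMatrix,
) -> dict:
    """Run mlma_scan per trait column of `pheno`; returns {trait: scan table}."""
    scans = {}
    for trait in traits:
        scans[trait] = mlma_scan(pheno[trait].to_numpy(dtype=float), covariates, grm, geno)
    return scans
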