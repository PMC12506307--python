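# Methods

## The association model

Each trait is analysed with the linear mixed model

    y = Xβ + g + e,    g ~ N(0, G σ²g),    e ~ N(0, I σ²e)

where `X` contains an intercept, one-hot contemporary-group (herd-year)
indicators with the first level dropped (singleton groups retained — their
indicator simply absorbs that animal's mean), per-animal genome-wide
heterozygosity (the proportion of heterozygous loci, a hybrid-content
covariate for multibreed data), and the first four principal components of
the column-standardised dosage matrix.  `G` is the VanRaden genomic
relationship matrix

    G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i))

with observed alt-allele frequencies; monomorphic variants are skipped.
The binary puberty trait is analysed on its observed 0/1 scale with the
same linear model — at these effect sizes the linear probability model
loses little against a threshold model and keeps all four traits on one
inferential footing.

**REML.**  With a single relationship matrix and an identity residual, the
restricted likelihood after eigenrotation of `G` depends on one parameter,
the variance ratio λ = σ²g/σ²e.  `reml_fit` maximises the profiled
restricted likelihood over log λ ∈ [−12, 12] by bounded scalar minimisation
(tolerance 1e-8, explicit comparison against the σ²g = 0 boundary).  This
is exact for the model — there is no iterative AI/EM machinery to tune —
and degenerate fits surface as errors rather than silent non-convergence.

**Per-variant tests.**  Variance components are estimated once on the null
model and held fixed (standard MLMA practice; no leave-one-chromosome-out by
default).  Each variant is tested by OLS in the whitened space
`V^(−1/2)(·)` with the fixed covariates projected out, which is the GLS
estimate under `V = σ²g G + σ²e I`.  The standard error uses the per-SNP
residual variance on `n − p − 1` degrees of freedom, so that when σ²g = 0
the scan agrees exactly — coefficients and standard errors — with ordinary
least squares of `y` on (covariates, SNP).  Two-sided p-values use the
standard normal on t = beta/se, the convention of downstream
summary-statistic tools.

## Multi-trait statistic

Signed t-values from the k single-trait scans are aligned on the common
variant set (effects flipped to a shared alt allele; variants missing from
any scan dropped) and combined per variant as `X² = tᵀV⁻¹t`, chi-square
with k degrees of freedom under the null.  `V` is the Pearson correlation
of t-values over **all** aligned variants (a `null_only` flag restricts to
|t| < 2 as a sensitivity option); if its smallest eigenvalue falls below
1e-6 it is shrunk toward the identity just enough to restore that floor.
The genome-wide significance threshold defaults to 1e-9
(0.05 / ~4.47e7 tests rounded to one significant figure), exposed as
`--alpha`.

## Conditional analysis from summary statistics

With centred genotypes, the multiple-regression normal equations are
`X'X = n·D·R·D` and `X'y_j = n·sd_j²·beta_j`, where `R` is the reference
correlation matrix and `D = diag(sd)`.  `conditional_scan` reports each
target's coefficient in the joint fit of {condition set ∪ target};
`joint_fit` returns the joint coefficients of a named set.  The phenotypic
variance is reconstructed per SNP from (beta, se, n, sd) — assuming the
marginal model was intercept + SNP with `n − 2` residual df — and medianed
across SNPs.  Genotype variances come from the reference panel's empirical
dosage variance rather than 2p(1−p), which is what makes the estimates
*exactly* equal to individual-level regression when the reference is the
GWAS sample (the correctness oracle in the tests).  SNP pairs farther apart
than 10 Mb, or on different chromosomes, are treated as unlinked; targets
with r² > 0.9 against any conditioning SNP are excluded and flagged rather
than estimated (both constants config-exposed).

**Mixed-model consistency.**  A mixed-model scan's effect estimates are OLS
estimates in the whitened space, not in raw genotype space.  Feeding them
into conditional algebra built on raw-genotype LD is inconsistent, and at
desk-scale relatedness the inconsistency is large enough to make iterative
conditioning diverge.  `gwas_lmm.whitened_reference` therefore exposes the
V^(−1/2)-whitened, covariate-projected genotype matrix; building the
`LdReference` from it (with `center=False`, since the whitened columns are
projected rather than mean-centred) makes summary-statistic conditioning
equal to the joint GLS fit.  The pipeline uses one whitened reference per
trait; expression summary statistics are plain OLS, so the per-gene
conditional eQTL analysis uses the raw-genotype reference.

## The integration loop

Starting from the aligned scans: (1) compute the multi-trait scan; (2)
greedily open 2 Mb windows centred on the most significant variants,
masking as it goes, while any variant passes the threshold; (3) per window,
take the most significant cis-eQTL per gene ("SNP set2" candidates;
deterministic tie-breaks by p, then position, then alleles) — when every
eQTL lead in a window is already fitted, or the window has no eQTL at all,
fall back to the window's lead GWAS variant; (4) recompute every
single-trait scan conditional on the full running set2, drop excluded
(collinear) variants, and recompute the multi-trait scan **with the
original V** — V is a genome-wide nuisance estimate, and re-estimating it
on conditioned statistics would be circular; (5) repeat, hard cap 20
iterations.  The per-gene conditional eQTL analysis conditions a gene's
expression statistics on its lead QTLs (expression threshold 1e-10,
Bonferroni-style) and counts additional independent signals by forward
stepwise conditioning.

## EHH and sweep diagnostics

EHH at position x for the carriers of a core allele is
`Σ_h C(n_h, 2) / C(c, 2)` over distinct haplotypes extending from the core
to x.  The implementation sorts carrier haplotypes lexicographically
outward from the core, records the first-difference depth of adjacent
sorted rows, and sweeps each flank once while merging runs; this is
O(c log c · L) and agrees exactly with brute-force pair enumeration (tested
on panels up to 20 haplotypes × 15 SNPs).  No early-termination cutoff is
applied; profiles run to the edge of the extracted region (an optional
EHH < 0.05 cutoff exists but is off by default), and the AUC is the
trapezoidal integral against physical position (bp), both flanks, so
0 ≤ AUC ≤ region length.

The permutation contrast between two core alleles pools the two carrier
haplotype sets, re-partitions them at random into groups of the original
sizes, recomputes both AUCs with each locus's own core, and reports the
two-sided `p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1)` with n_perm = 10,000
by default.  The Wilcoxon comparison pairs allele EHH values at matched SNP
positions, pools across loci, drops zero differences, and reports a signed
statistic (W⁺ − W⁻, antisymmetric under allele swap).  The count test is a
df = 1 goodness-of-fit chi-square of "k of n loci show the longer haplotype
on the focal allele" against 50:50; the two-locus co-inheritance test is a
Pearson chi-square of independence on the 3 × 3 genotype table (df = 4;
zero-margin classes collapsed with a warning).

## The simulator and what it does (not) emulate

A diploid Wright–Fisher population of 2 breeds × 300 individuals evolves
for 10 generations as one ancestral population, splits, and evolves 55 more
generations per breed; during the final 50 generations the core variant is
selected with genic fitness 1, 1+s, 1+2s, s = 0.05, from an initial
frequency of 0.2 (expected final frequency ≈ 0.75, so the allele usually
remains polymorphic).  Crossbreds (30% of the final cohort, n ≈ 857 total)
are F1s from inter-breed matings in the last generation.  Gametes recombine
by a Poisson crossover process at 1e-8 per bp (~1 cM/Mb) over a 2 Mb,
1,000-SNP region.

Two unlinked chromosomes are transmitted through the same pedigree: the
focal region, and a neutral background chromosome that carries the
polygenic trait background and feeds the GRM and the genotype PCs — playing
the role the rest of the genome plays in a real study.  Without it, a
region-only GRM absorbs the focal QTL entirely (a proximal-contamination
artefact).  Population sizes and generation counts were chosen so the
realised GRM has an off-diagonal spread (sd ≈ 0.12) comparable to a
strongly structured livestock cohort rather than the far higher relatedness
a small long-running population accumulates.

Phenotypes: liability = QTL dosage × effect + polygenic term (≈200
background SNPs, scaled to h² = 0.3) + contemporary-group effect
(5 groups, sd 0.5) + correlated residual (variance 1 − h²; modest positive
residual correlations).  Default QTL effects are antagonistic — height
+1.0, weight +1.0, BCS −0.7, puberty liability −0.8 residual-SD units —
sized so single- and multi-trait power at the 1e-9 threshold is ≈ 1 at
n ≈ 857.  Puberty is thresholded at the empirical liability quantile
matching a 0.42 prevalence.  Expression = eQTL dosage × 1.5 + N(0, 1)
noise, with an optional second independent eQTL; planted eQTL indices snap
to the nearest variant with MAF ≥ 0.05, since drift can fix the originally
chosen site.

**Neutral control for the sweep contrast.**  Carrier-class homozygosity is
frequency-dependent: a minor allele's carriers trivially share longer
haplotypes.  A neutral run with the core starting at 0.2 therefore shows
the "selected" allele winning the AUC contrast for the wrong reason.  The
neutral control is run with the core at initial frequency 0.5, where the
two alleles are exchangeable and the win fraction is 50% by symmetry; the
sweep arm's excess over 50% — despite the swept allele *ending* as the
major allele — is the sweep signature.

Known limitations: founder haplotypes are drawn site-independently (no
ancestral coalescent LD — all output LD comes from drift, the split,
admixture and the sweep); the polygenic backgrounds of the four traits are
independent (trait correlations enter through the shared QTL and the
residual correlation matrix); selection is genic at a single site; breeds
share one founding population rather than deep divergence.  Passing tests
on this generator demonstrate the estimators' correctness and the
qualitative sweep mechanism, not calibration against real cattle LD.

## Numerical choices

- Coordinates are 1-based inclusive in files and `pos` columns, 0-based
  internally; conversions only at I/O boundaries.
- Alt-allele dosage everywhere; effect signs always refer to the alt
  allele; allele harmonisation flips sign and frequency when a scan's
  ref/alt are swapped.
- Missing genotypes and multi-allelic records are rejected (imputed,
  biallelic input is assumed); MAF filtering is strict (`maf > t`).
- GRM ridge 1e-6 before declaring non-PSD; t-correlation eigenvalue floor
  1e-6; collinear scan variants flagged with se = +inf, p = 1 rather than
  dropped silently.
- Window arithmetic: a width-w window on lead position q is
  [max(1, q − w/2 + 1), q + w/2]; greedy leads are never inside previously
  opened windows, though window spans may overlap near dense signals.
- All simulation randomness flows from one root seed
  (`numpy.random.default_rng`); fixture bundles are byte-identical under a
  fixed seed.

## Problem sizes

Defaults throughout are desk-scale by design: n ≈ 857 animals, 2 × 1,000
SNPs, 50-replicate batches for the sweep contrast, 8 replicates for full
end-to-end integration recovery, and 20 for the two-eQTL conditional case.
All are config-exposed; the estimators themselves are dimension-agnostic.
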