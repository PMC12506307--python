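"""Iterative integration of multi-trait GWAS with cis-eQTL summary statistics.

The loop mirrors how pleiotropic QTL candidates are refined when expression
data are available only as summary statistics:

1. combine the single-trait scans into the multi-trait chi-square scan;
2. open non-overlapping 2 Mb windows centred on the most significant
   variants (greedy, masking as it goes) while any variant passes the
   threshold;
3. in each window take the most significant cis-eQTL per gene as a putative
   causal variant (falling back to the window's lead GWAS variant when no
   eQTL overlaps) and append it to the running condition set ("SNP set2");
4. re-derive every single-trait scan conditional on set2 via the
   summary-statistic machinery, drop variants collinear with set2, and
   recompute the multi-trait scan with the *original* trait-correlation
   matrix V (a genome-wide nuisance quantity, deliberately not re-estimated
   on conditioned statistics);
5. repeat until no variant is significant or nothing new can be fitted.

A per-gene conditional eQTL analysis (how many independent expression
signals remain once the lead QTLs are fitted) is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cojo import LdReference, conditional_scan
from .mgwas import MGWAS_ALPHA, align_traits, estimate_t_correlation, mgwas_scan

WINDOW_BP = 2_000_000
EQTL_ALPHA = 1e-10  # Bonferroni-style expression threshold
MAX_ITERATIONS = 20


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    lead_id: str
    lead_p: float

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == str(self.chrom) and self.start <= pos <= self.end


@dataclass
class IntegrationState:
    set1: list = field(default_factory=list)  # strong-association variants, 1st round
    set2: list = field(default_factory=list)  # putative causal variants fitted so far
    iterations: list = field(default_factory=list)  # per-round diagnostics
    windows: list = field(default_factory=list)  # all windows ever opened
    final_mgwas: pd.DataFrame | None = None
    final_scans: dict | None = None
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def select_windows(mgwas_table: pd.DataFrame, alpha: float, width: int = WINDOW_BP):
    """Greedy non-overlapping windows centred on the most significant variants.

    Repeatedly takes the smallest remaining p-value below ``alpha``, opens a
    window of ``width`` bp centred on it ([pos − width/2 + 1, pos + width/2],
    clamped at position 1), and masks every variant inside before looking for
    the next lead.
    """
    half = width // 2
    tab = mgwas_table[["chrom", "pos", "id", "p"]].reset_index(drop=True)
    available = np.ones(len(tab), dtype=bool)
    p = tab["p"].to_numpy(dtype=float)
    pos = tab["pos"].to_numpy(dtype=np.int64)
    chrom = tab["chrom"].to_numpy()
    windows = []
    while True:
        masked_p = np.where(available, p, np.inf)
        i = int(np.argmin(masked_p))
        if not np.isfinite(masked_p[i]) or masked_p[i] >= alpha:
            break
        start = max(1, int(pos[i]) - half + 1)
        end = int(pos[i]) + half
        win = Window(str(chrom[i]), start, end, str(tab["id"].iloc[i]), float(p[i]))
        windows.append(win)
        inside = (chrom == chrom[i]) & (pos >= start) & (pos <= end)
        available &= ~inside
    return windows


def pick_lead_eqtl(window: Window, eqtl_table: pd.DataFrame) -> list:
    """Most significant cis-eQTL variant per gene inside the window.

    Ties broken by p, then position, then allele strings; variants shared by
    several genes are returned once.  Returns variant ids (``id`` column if
    present, otherwise chrom:pos:ref:alt).
    """
    tab = eqtl_table.copy()
    if "id" not in tab.columns:
        tab["id"] = (
            tab["chrom"].astype(str) + ":" + tab["pos"].astype(str)
            + ":" + tab["ref"].astype(str) + ":" + tab["alt"].astype(str)
        )
    inside = (
        (tab["chrom"].astype(str) == str(window.chrom))
        & (tab["pos"] >= window.start)
        & (tab["pos"] <= window.end)
    )
    tab = tab[inside]
    if tab.empty:
        return []
    tab = tab.sort_values(["p", "pos", "ref", "alt"], kind="mergesort")
    leads = tab.groupby("gene", sort=False).head(1)
    leads = leads.sort_values(["p", "pos", "ref", "alt"], kind="mergesort")
    out = []
    for vid in leads["id"]:
        if vid not in out:
            out.append(vid)
    return out


def _usable(scan: pd.DataFrame) -> pd.DataFrame:
    out = scan
    if "excluded" in out.columns:
        out = out[~out["excluded"].astype(bool)]
    out = out[np.isfinite(out["beta"]) & np.isfinite(out["se"])]
    return out.reset_index(drop=True)


def iterate_integration(
    scans: dict,
    eqtl_table: pd.DataFrame,
    ld_ref: LdReference,
    alpha: float = MGWAS_ALPHA,
    width: int = WINDOW_BP,
    max_iter: int = MAX_ITERATIONS,
) -> IntegrationState:
    """Run the iterative conditional-integration loop until nothing is significant.

    ``scans`` maps trait name → marginal summary statistics (the original,
    unconditioned scans; conditioning is always applied to these with the
    full running set2).  ``ld_ref`` is either one LdReference shared by all
    traits or a mapping trait → LdReference (use the whitened per-trait
    reference from :func:`pleiosweep.gwas_lmm.whitened_reference` for
    mixed-model scans, which makes the conditioning exact).  The
    trait-correlation matrix V is estimated once from the original aligned
    t-values and reused every round.
    """
    state = IntegrationState()
    traits = list(scans.keys())
    refs = ld_ref if isinstance(ld_ref, dict) else {tr: ld_ref for tr in traits}
    any_ref = next(iter(refs.values()))

    tmat0 = align_traits({tr: _usable(scans[tr]) for tr in traits}, traits)
    v0 = estimate_t_correlation(tmat0)
    table0 = mgwas_scan(tmat0, alpha)
    state.set1 = list(table0.loc[table0["p"] < alpha, "id"])

    current = {tr: scans[tr] for tr in traits}
    table = table0
    for _ in range(max_iter):
        windows = select_windows(table, alpha, width)
        n_sig = int((table["p"] < alpha).sum())
        if not windows:
            state.iterations.append(
                {"windows": [], "added": [], "n_significant": n_sig}
            )
            state.converged = True
            break
        added = []

        def _eligible(vid):
            if vid in state.set2 or vid in added:
                return False
            try:
                any_ref.index_of([vid])
            except KeyError:
                return False
            return all((scans[tr]["id"] == vid).any() for tr in traits)

        for win in windows:
            picked = [v for v in pick_lead_eqtl(win, eqtl_table) if _eligible(v)]
            if not picked and _eligible(win.lead_id):
                # no new eQTL lead in this window: fall back to its top
                # multi-trait GWAS variant so the loop keeps making progress
                picked = [win.lead_id]
            added.extend(picked)
        state.windows.extend(windows)
        state.iterations.append(
            {"windows": [w.lead_id for w in windows], "added": list(added),
             "n_significant": n_sig}
        )
        if not added:
            # Nothing new can be fitted (e.g. every candidate already in set2);
            # the remaining signal cannot be conditioned away.
            break
        state.set2.extend(added)
        current = {
            tr: conditional_scan(scans[tr], state.set2, refs[tr]) for tr in traits
        }
        tmat = align_traits({tr: _usable(current[tr]) for tr in traits}, traits)
        tmat.v = v0
        table = mgwas_scan(tmat, alpha)
    else:
        raise RuntimeError(
            f"integration did not terminate within {max_iter} iterations; "
            f"state: set2={state.set2}, per-round={state.iterations}"
        )

    state.final_mgwas = table
    state.final_scans = current
    return state


def conditional_eqtl(
    gene_stats: pd.DataFrame,
    lead_qtls,
    ld_ref: LdReference,
    alpha: float = EQTL_ALPHA,
    max_signals: int = 10,
):
    """Conditional eQTL analysis for one gene.

    Conditions the gene's expression summary statistics on the lead QTLs,
    then counts independent remaining signals by forward stepwise
    conditioning (add the top remaining significant variant, recondition,
    repeat).  Returns ``(conditioned_stats, n_additional, n_total)`` where
    ``n_total = n_additional + len(lead_qtls)`` — the gene's independent
    signal count when each lead QTL is itself one signal.
    """
    lead_qtls = list(lead_qtls)
    if gene_stats.empty:
        raise ValueError("gene has no eQTL rows")
    conditioned = conditional_scan(gene_stats, lead_qtls, ld_ref)

    cond_set = list(lead_qtls)
    n_additional = 0
    current = conditioned
    while n_additional < max_signals:
        usable = _usable(current)
        sig = usable[usable["p"] < alpha]
        if sig.empty:
            break
        top = sig.sort_values(["p", "pos"], kind="mergesort")["id"].iloc[0]
        cond_set.append(top)
        n_additional += 1
        current = conditional_scan(gene_stats, cond_set, ld_ref)
    return conditioned, n_additional, n_additional + len(lead_qtls)
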