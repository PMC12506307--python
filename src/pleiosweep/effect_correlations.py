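"""Pairwise Pearson correlations of SNP effects between traits.

Correlations are computed on signed t-values (effect / SE), which puts
traits with different units and information content on a comparable scale;
raw-beta correlations are available as a sensitivity option.  Supported
groupings: genome-wide, per chromosome, and a designated variant subset
(e.g. the lead QTLs recovered by the eQTL integration).  Note the
genome-wide r is the pooled computation over all variants, which is not the
mean of per-chromosome r values.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .mgwas import TMatrix


def _pairwise(t: np.ndarray, traits, group_label: str, use_beta_cols=None) -> list:
    rows = []
    for i, j in combinations(range(len(traits)), 2):
        n = t.shape[0]
        if n < 3:
            warnings.warn(f"group {group_label!r} has {n} variants; correlation undefined")
            r = np.nan
        else:
            r = float(np.corrcoef(t[:, i], t[:, j])[0, 1])
        rows.append(
            {"group": group_label, "trait1": traits[i], "trait2": traits[j],
             "r": r, "n_variants": n}
        )
    return rows


def t_correlations(
    tmat: TMatrix,
    grouping: str = "genome",
    subset_ids=None,
) -> pd.DataFrame:
    """Long-format trait-pair correlation table for the requested grouping.

    grouping: ``"genome"`` (all aligned variants), ``"per_chromosome"``
    (one group per chromosome), or ``"subset"`` (restrict to
    ``subset_ids``).
    """
    rows = []
    if grouping == "genome":
        rows += _pairwise(tmat.t, tmat.traits, "genome")
    elif grouping == "per_chromosome":
        chroms = tmat.variants["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            rows += _pairwise(tmat.t[mask], tmat.traits, str(chrom))
    elif grouping == "subset":
        if subset_ids is None:
            raise ValueError("subset grouping requires subset_ids")
        mask = tmat.variants["id"].isin(list(subset_ids)).to_numpy()
        rows += _pairwise(tmat.t[mask], tmat.traits, "subset")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return pd.DataFrame(rows)


def qtl_expression_trait_correlation(
    expression_effects, trait_effects: pd.DataFrame
) -> pd.Series:
    """Pearson r between QTL effects on expression and on each trait.

    ``expression_effects`` is a length-q vector of signed t-values of the
    candidate QTLs on their gene's expression; ``trait_effects`` is a q × k
    frame of signed t-values of the same QTLs on each trait.  Fewer than
    three complete pairs yields NaN for that trait.
    """
    e = np.asarray(expression_effects, dtype=float)
    out = {}
    for trait in trait_effects.columns:
        t = trait_effects[trait].to_numpy(dtype=float)
        ok = np.isfinite(e) & np.isfinite(t)
        if ok.sum() < 3:
            out[trait] = np.nan
        else:
            out[trait] = float(np.corrcoef(e[ok], t[ok])[0, 1])
    return pd.Series(out, name="r")
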