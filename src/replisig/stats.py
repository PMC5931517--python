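"""Cohort-level statistics and genotype classification.

Proofreading status is called from a tumor's POLE/POLD1 mutation list: a
sample is exo* when it carries at least one missense mutation inside the
polymerase's exonuclease domain (POLE codons 268-471, POLD1 codons
304-517); out-of-domain, splice-site and loss-of-function mutations are
discounted.  The recurrent POLE hotspots P286R and V411L are labelled.
Group comparisons use Fisher's exact test on 2x2 crosstabs and one-tailed
Wilcoxon rank-sum tests on signature fractions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats as st

POLE_EXO_DOMAIN = (268, 471)
POLD1_EXO_DOMAIN = (304, 517)
POLE_HOTSPOTS = {286: "P286R", 411: "V411L"}

#: consequence vocabulary; anything else is skipped with a warning
MISSENSE = {"missense"}
DISCOUNTED = {"nonsense", "frameshift", "splice_site", "stop_gained",
              "synonymous", "inframe_del", "inframe_ins"}


def classify_exo_status(
    gene_mutations: pd.DataFrame,
    gene: str = "POLE",
    domain: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-sample exonuclease-domain status from a gene-mutation table.

    ``gene_mutations`` columns: sample, gene, codon, consequence (and
    optionally protein_change).  Returns one row per sample seen, with
    status 'exo*' or 'WT' and a hotspot label for POLE P286R/V411L.
    Idempotent and order-invariant over the mutation list."""
    if domain is None:
        domain = POLE_EXO_DOMAIN if gene == "POLE" else POLD1_EXO_DOMAIN
    lo, hi = domain
    muts = gene_mutations[gene_mutations["gene"] == gene]
    status: dict[str, str] = {}
    hotspot: dict[str, str | None] = {}
    for s in muts["sample"].unique():
        status[s] = "WT"
        hotspot[s] = None
    for _, row in muts.iterrows():
        cons = str(row["consequence"]).lower()
        if cons not in MISSENSE:
            if cons not in DISCOUNTED:
                warnings.warn(
                    f"unknown consequence {cons!r}; record skipped",
                    stacklevel=2,
                )
            continue
        codon = int(row["codon"])
        if not lo <= codon <= hi:
            continue
        s = row["sample"]
        status[s] = "exo*"
        if gene == "POLE" and codon in POLE_HOTSPOTS:
            label = POLE_HOTSPOTS[codon]
            pc = str(row.get("protein_change", "") or "")
            if not pc or pc == label:
                hotspot[s] = label
    return pd.DataFrame(
        {
            "sample": list(status),
            "status": [status[s] for s in status],
            "hotspot": [hotspot[s] for s in status],
        }
    )


def fisher_exact(table, sided: str = "two") -> float:
    """Exact hypergeometric p-value for a 2x2 count table.

    ``sided`` is 'two' (minimum-likelihood two-sided), 'greater' or 'less'.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    return float(st.fisher_exact(t, alternative=alternative).pvalue)


def one_tailed_ranksum(group, reference, direction: str = "greater") -> float:
    """One-tailed Wilcoxon rank-sum p-value that ``group`` is shifted in
    ``direction`` relative to ``reference``.

    Ties are midranked; small tie-free samples use the exact distribution,
    otherwise a normal approximation with continuity correction."""
    x = np.asarray(group, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (no_ties and x.size <= 20 and y.size <= 20) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative=direction, method=method,
                          use_continuity=True)
    return float(res.pvalue)


def crosstab(
    annotations: pd.DataFrame, row_var: str, col_var: str
) -> pd.DataFrame:
    """Contingency table with an explicit 'missing' category."""
    df = annotations[[row_var, col_var]].copy()
    for c in (row_var, col_var):
        col = df[c].astype(object)
        df[c] = col.where(col.notna(), "missing")
    if not len(df):
        return pd.DataFrame()
    return pd.crosstab(df[row_var], df[col_var], dropna=False)
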