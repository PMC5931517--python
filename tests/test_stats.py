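"""Genotype classification and cohort-level statistics."""

from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import replisig as rs


def _hypergeom_two_sided(table):
    """Enumeration oracle: two-sided Fisher p by summing the probabilities
    of all tables (fixed margins) no more likely than the observed one."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = st.hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = st.hypergeom.pmf(x, n, col1, row1)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return p


def test_fisher_reproduces_printed_hotspot_association():
    """2/30 hotspot (P286R/V411L) vs 13/20 other-exo* MSI-H tumors."""
    p = rs.fisher_exact([[2, 28], [13, 7]])
    assert f"{p:.1e}" == "1.6e-05"


def test_fisher_proportional_table_is_null():
    assert rs.fisher_exact([[10, 20], [5, 10]]) == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = rng.integers(0, 8, size=(2, 2))
        if t.sum() == 0:
            continue
        assert rs.fisher_exact(t) == pytest.approx(_hypergeom_two_sided(t))


def test_fisher_sidedness_and_errors():
    t = [[2, 28], [13, 7]]
    one = min(rs.fisher_exact(t, "less"), rs.fisher_exact(t, "greater"))
    assert rs.fisher_exact(t, "two") >= one
    with pytest.raises(ValueError):
        rs.fisher_exact([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        rs.fisher_exact([[-1, 2], [3, 4]])


def test_ranksum_complete_separation_exact_minimum():
    group = np.arange(100, 110, dtype=float)
    ref = np.arange(0, 10, dtype=float)
    p = rs.one_tailed_ranksum(group, ref, "greater")
    assert p == pytest.approx(1 / comb(20, 10))


def test_ranksum_identical_distributions_near_half():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=400), rng.normal(size=400)
    p = rs.one_tailed_ranksum(x, y, "greater")
    assert 0.2 < p < 0.8


def test_ranksum_group_swap_symmetry():
    rng = np.random.default_rng(2)
    x, y = rng.normal(1.0, 1, 30), rng.normal(0.0, 1, 25)
    assert rs.one_tailed_ranksum(x, y, "greater") == pytest.approx(
        rs.one_tailed_ranksum(y, x, "less")
    )
    with pytest.raises(ValueError):
        rs.one_tailed_ranksum([], [1.0])


def _gene_muts(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "codon", "consequence"])


def test_exo_status_hotspot_and_domain_rules():
    tbl = _gene_muts(
        [
            ("s1", "POLE", 286, "missense"),   # hotspot inside 268-471
            ("s2", "POLE", 500, "missense"),   # outside the domain
            ("s3", "POLE", 300, "nonsense"),   # LoF discounted
            ("s4", "POLE", 411, "missense"),   # V411L hotspot
            ("s5", "POLD1", 310, "missense"),
        ]
    )
    res = rs.classify_exo_status(tbl, "POLE").set_index("sample")
    assert res.loc["s1", "status"] == "exo*" and res.loc["s1", "hotspot"] == "P286R"
    assert res.loc["s2", "status"] == "WT"
    assert res.loc["s3", "status"] == "WT"
    assert res.loc["s4", "hotspot"] == "V411L"
    pold1 = rs.classify_exo_status(tbl, "POLD1").set_index("sample")
    assert pold1.loc["s5", "status"] == "exo*"


def test_exo_status_order_invariant_and_idempotent():
    rows = [
        ("s1", "POLE", 286, "missense"),
        ("s1", "POLE", 600, "missense"),
        ("s1", "POLE", 300, "nonsense"),
    ]
    a = rs.classify_exo_status(_gene_muts(rows), "POLE")
    b = rs.classify_exo_status(_gene_muts(rows[::-1]), "POLE")
    assert a.set_index("sample").loc["s1", "status"] == "exo*"
    assert b.set_index("sample").loc["s1", "status"] == "exo*"


def test_unknown_consequence_warns_and_skips():
    tbl = _gene_muts([("s1", "POLE", 286, "mystery")])
    with pytest.warns(UserWarning, match="unknown consequence"):
        res = rs.classify_exo_status(tbl, "POLE").set_index("sample")
    assert res.loc["s1", "status"] == "WT"


def test_crosstab_matches_generator_truth(small_cohort):
    tab = rs.crosstab(small_cohort.annotations, "genotype", "msi_status")
    truth = small_cohort.annotations.groupby(["genotype", "msi_status"]).size()
    for (g, m), n in truth.items():
        assert tab.loc[g, m] == n
    assert tab.to_numpy().sum() == len(small_cohort.annotations)


def test_crosstab_empty_and_missing_category():
    empty = rs.crosstab(pd.DataFrame(columns=["a", "b"]), "a", "b")
    assert empty.empty
    df = pd.DataFrame(dict(a=["x", "y", "x"], b=["u", None, "v"]))
    tab = rs.crosstab(df, "a", "b")
    assert "missing" in tab.columns
    assert tab.loc["y", "missing"] == 1
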