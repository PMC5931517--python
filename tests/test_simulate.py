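"""Synthetic-cohort generator: determinism, conservation, structure."""

import numpy as np
import pytest

import replisig as rs


def _uniform_burdens(lo, hi):
    return {
        g: (lo, hi)
        for g in ("POLE-MSS", "POLE-MSI", "POLD1-MSI", "MSI", "MSS", "POLD1-MSS")
    }


def test_empty_cohort_is_valid(tmp_path):
    cfg = rs.CohortConfig(n_samples=0, seed=1)
    coh = rs.generate_cohort(cfg)
    assert len(coh.mutations) == 0
    assert len(coh.annotations) == 0
    coh.write(tmp_path)  # empty files are still well-formed
    assert (tmp_path / "mutations.maf.tsv").exists()


def test_same_seed_identical_output():
    cfg = dict(n_samples=5, seed=42, burden_range=_uniform_burdens(100, 400))
    a = rs.generate_cohort(rs.CohortConfig(**cfg))
    b = rs.generate_cohort(rs.CohortConfig(**cfg))
    assert a.mutations.equals(b.mutations)
    assert a.annotations.equals(b.annotations)
    assert a.reference == b.reference


def test_single_signature_counts_match_multinomial_tally():
    truth = {"E": rs.default_truth_signatures(3)["E"]}
    cfg = rs.CohortConfig(
        n_samples=1, seed=3, truth_signatures=truth,
        genotype_mix={"POLE-MSS": 1.0},
        burden_range={"POLE-MSS": (1000, 1000)},
        genotype_signature_weights={"POLE-MSS": {"E": 1.0}},
    )
    coh = rs.generate_cohort(cfg)
    assert len(coh.mutations) == 1000
    # brute-force recount of the emitted list equals the catalog column
    recount = np.bincount(coh.mutations["channel"].to_numpy(), minlength=1544)
    cat = rs.build_catalog(coh.mutations)
    assert (cat.values[:, 0] == recount).all()


def test_per_sample_burden_conservation(small_cohort):
    emitted = small_cohort.mutations.groupby("sample").size()
    drawn = small_cohort.truth_exposures.sum(axis=0)
    for s in drawn.index:
        assert emitted.get(s, 0) == drawn[s]


def test_ccf_interval_invariant(small_cohort):
    m = small_cohort.mutations
    assert (m["ccf_lo"] <= m["ccf"] + 1e-12).all()
    assert (m["ccf"] <= m["ccf_hi"] + 1e-12).all()


def test_every_mutation_sample_annotated(small_cohort):
    assert set(small_cohort.mutations["sample"]) <= set(
        small_cohort.annotations["sample"]
    )
    L = len(small_cohort.reference)
    assert small_cohort.mutations["pos"].between(0, L - 1).all()


def test_reference_tracks_partition():
    seq, timing, strand = rs.generate_reference_tracks(400, 4, seed=0)
    assert len(seq) == 400
    assert list(timing["start"]) == [0, 100, 200, 300]
    assert list(timing["end"]) == [100, 200, 300, 400]
    # no overlap, union covers the sequence (timing and strand tracks)
    for track in (timing, strand):
        assert (track["start"].to_numpy()[1:] == track["end"].to_numpy()[:-1]).all()
        assert track["start"].iloc[0] == 0 and track["end"].iloc[-1] == 400


def test_reference_tracks_deterministic_and_errors():
    s1, _, _ = rs.generate_reference_tracks(300, 4, seed=9)
    s2, _, _ = rs.generate_reference_tracks(300, 4, seed=9)
    assert s1 == s2
    with pytest.raises(ValueError):
        rs.generate_reference_tracks(0, 4)
    with pytest.raises(ValueError):
        rs.generate_reference_tracks(10, 4)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        rs.CohortConfig(genotype_mix={"MSS": 0.5}).validate()
    with pytest.raises(ValueError):
        rs.CohortConfig(truth_signatures={}).validate()
    with pytest.raises(ValueError):
        rs.CohortConfig(
            burden_range={**rs.CohortConfig().burden_range, "MSS": (10, 5)}
        ).validate()
    with pytest.raises(ValueError):
        rs.CohortConfig(order_scenario="both_first").validate()


def test_truth_signatures_are_well_separated():
    sigs = rs.default_truth_signatures(0)
    names = list(sigs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = sigs[a], sigs[b]
            cos = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
            assert cos < 0.35, (a, b, cos)


def test_pole_first_scenario_enriches_clonal_E():
    """Under pole_first, the clonal subset's signature-E mass fraction
    exceeds the subclonal subset's."""
    cfg = rs.CohortConfig(
        n_samples=4, seed=11, order_scenario="pole_first",
        genotype_mix={"POLE-MSI": 1.0},
        burden_range={"POLE-MSI": (2000, 3000)},
        genotype_signature_weights={"POLE-MSI": {"C": 0.9, "M": 0.1}},
        clonal_fraction=0.5,
    )
    coh = rs.generate_cohort(cfg)
    m = coh.mutations
    lab = rs.partition_clonality(m)
    for subset, other in ((lab == "clonal", lab == "subclonal"),):
        e_clonal = (m.loc[subset, "truth_signature"] == "E").mean()
        e_sub = (m.loc[other, "truth_signature"] == "E").mean()
        assert e_clonal > e_sub


def test_cohort_write_round_trip(tmp_path, small_cohort):
    from replisig.catalog import read_fasta

    small_cohort.write(tmp_path)
    back = rs.read_maf(tmp_path / "mutations.maf.tsv")
    assert len(back) == len(small_cohort.mutations)
    assert read_fasta(tmp_path / "reference.fa") == small_cohort.reference
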