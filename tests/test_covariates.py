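"""Replication-timing enrichment and strand asymmetry."""

import numpy as np
import pytest

import replisig as rs
from replisig.covariates import bootstrap_patients, _sub_slice
from replisig.channels import N_SNV_CHANNELS


def _toy_model(W, H, n_samples=None):
    K = W.shape[1]
    P = H.shape[1]
    return rs.SignatureModel(
        W=W, H=H,
        channel_labels=tuple(f"c{i}" for i in range(W.shape[0])),
        sample_labels=tuple(f"p{j}" for j in range(P)),
        signature_names=tuple(f"S{k}" for k in range(K)),
        K_effective=K, objective_trace=[0.0],
    )


def test_lambda_uniform_single_signature():
    W = np.full((1536, 1), 1 / 1536)
    H = np.array([[100.0]])
    lam = rs.lambda_channel_burden(_toy_model(W, H), 0)
    assert np.allclose(lam, 100 / 1536)


def test_lambda_conserves_attributed_burden(recovery_cohort):
    model = rs.model_from_truth(recovery_cohort)
    for p in model.sample_labels[:5]:
        lam = rs.lambda_channel_burden(model, p)
        j = model.sample_labels.index(p)
        assert lam.sum() == pytest.approx(model.H[:, j].sum())


def test_lambda_hand_matrix_product():
    W = np.array([[0.2, 0.5], [0.8, 0.5]])
    H = np.array([[10.0], [4.0]])
    lam = rs.lambda_channel_burden(_toy_model(W, H), 0)
    assert np.allclose(lam, [0.2 * 10 + 0.5 * 4, 0.8 * 10 + 0.5 * 4])


def _uniform_track(n_per_bin_ctx=10, bins=("Q1", "Q2", "Q3", "Q4")):
    per_bin = np.full((len(bins), N_SNV_CHANNELS), n_per_bin_ctx, dtype=np.int64)
    return rs.OpportunityTrack(per_bin.sum(axis=0), per_bin, tuple(bins))


def test_expected_count_whole_genome_bin():
    track = rs.OpportunityTrack(
        np.full(N_SNV_CHANNELS, 7, dtype=np.int64),
        np.full((1, N_SNV_CHANNELS), 7, dtype=np.int64),
        ("all",),
    )
    lam = np.zeros(N_SNV_CHANNELS)
    sl = _sub_slice("C>T")
    lam[sl] = 0.5
    assert rs.expected_bin_count(lam, track, "C>T", "all") == pytest.approx(
        lam[sl].sum()
    )


def test_expected_count_uniform_quarters_and_skewed():
    track = _uniform_track()
    lam = np.zeros(N_SNV_CHANNELS)
    lam[_sub_slice("C>A")] = 1.0
    for b in track.bin_labels:
        assert rs.expected_bin_count(lam, track, "C>A", b) == pytest.approx(256 / 4)
    # skewed: one channel holds 70% of its opportunities in Q4
    per_bin = np.full((4, N_SNV_CHANNELS), 10, dtype=np.int64)
    per_bin[:, 0] = [1, 1, 1, 7]
    skew = rs.OpportunityTrack(per_bin.sum(axis=0), per_bin, ("Q1", "Q2", "Q3", "Q4"))
    lam = np.zeros(N_SNV_CHANNELS)
    lam[0] = 20.0  # channel 0 is a C>A channel
    lam[1] = 10.0
    # hand-computed: 20 * 7/10 + 10 * 10/40
    assert rs.expected_bin_count(lam, skew, "C>A", "Q4") == pytest.approx(
        20 * 0.7 + 10 * 0.25
    )


def test_expected_count_inconsistent_reference_rejected():
    track = _uniform_track()
    track.global_counts = track.global_counts.copy()
    track.bin_counts = track.bin_counts.copy()
    track.global_counts[5] = 0
    track.bin_counts[:, 5] = 0
    lam = np.zeros(N_SNV_CHANNELS)
    lam[5] = 3.0
    with pytest.raises(ValueError):
        rs.expected_bin_count(lam, track, "C>A", "Q1")


def test_expected_counts_sum_to_lambda_exactly(recovery_cohort):
    """Sum over bins of the expected counts recovers the attributed burden."""
    model = rs.model_from_truth(recovery_cohort)
    opp = rs.count_opportunities(
        recovery_cohort.reference, recovery_cohort.timing_track
    )
    for p in model.sample_labels[:4]:
        lam = rs.lambda_channel_burden(model, p)
        for sub in ("C>A", "C>T"):
            total = sum(
                rs.expected_bin_count(lam, opp, sub, b) for b in opp.bin_labels
            )
            assert total == pytest.approx(lam[:N_SNV_CHANNELS][_sub_slice(sub)].sum())


def test_observed_counts_conserved(recovery_cohort):
    model = rs.model_from_truth(recovery_cohort)
    opp = rs.count_opportunities(
        recovery_cohort.reference, recovery_cohort.timing_track
    )
    samples = list(recovery_cohort.annotations["sample"])[:10]
    prof = rs.timing_profile(
        recovery_cohort.mutations, samples, model, opp, n_boot=10, seed=0
    )
    snv = recovery_cohort.mutations[
        (recovery_cohort.mutations["variant_class"] == "SNV")
        & recovery_cohort.mutations["sample"].isin(samples)
    ]
    for sub in ("C>A", "C>T"):
        sub_idx = rs.channels.SUBSTITUTION_LABELS.index(sub)
        n = (snv["channel"] // 256 == sub_idx).sum()
        got = prof.table.loc[prof.table["substitution"] == sub, "observed"].sum()
        assert got == n


def test_late_bin_rate_bias_detected():
    cfg = rs.CohortConfig(
        n_samples=10, seed=31, genotype_mix={"POLE-MSS": 1.0},
        burden_range={"POLE-MSS": (3000, 5000)},
        genotype_signature_weights={"POLE-MSS": {"E": 0.8, "B": 0.2}},
        timing_bias={"Q4": 2.0},
    )
    coh = rs.generate_cohort(cfg)
    model = rs.model_from_truth(coh)
    opp = rs.count_opportunities(coh.reference, coh.timing_track)
    prof = rs.timing_profile(
        coh.mutations, list(coh.annotations["sample"]), model, opp,
        n_boot=200, seed=1,
    )
    for sub in ("C>A", "C>T"):
        cell = prof.cell(sub, "Q4")
        # enrichment of the doubled bin: 2 / (mean rate factor ~1.25)
        assert cell["enrichment"] == pytest.approx(1.6, abs=0.15)
        early = prof.cell(sub, "Q1")["enrichment"]
        assert cell["enrichment"] > early


def test_bootstrap_singleton_and_determinism():
    obs = np.array([[[4.0, 6.0]]])
    exp = np.array([[[5.0, 5.0]]])
    sd = bootstrap_patients(obs, exp, n_boot=50, seed=0)
    assert np.allclose(sd, 0.0, atol=1e-12)  # resampling a singleton
    obs2 = np.random.default_rng(1).poisson(20, size=(6, 1, 2)).astype(float)
    exp2 = np.full((6, 1, 2), 20.0)
    a = bootstrap_patients(obs2, exp2, n_boot=100, seed=3)
    b = bootstrap_patients(obs2, exp2, n_boot=100, seed=3)
    assert (a == b).all()


def test_bootstrap_sd_converges():
    rng = np.random.default_rng(2)
    obs = rng.poisson(50, size=(12, 1, 1)).astype(float)
    exp = np.full((12, 1, 1), 50.0)
    sd_small = bootstrap_patients(obs, exp, n_boot=1000, seed=0)
    sd_big = bootstrap_patients(obs, exp, n_boot=10_000, seed=1)
    assert sd_small == pytest.approx(sd_big, rel=0.2)


def test_dominated_sample_selection():
    import pandas as pd

    frac = pd.DataFrame(
        {"E1": [0.5, 0.8, 0.4], "E2": [0.3, 0.1, 0.1], "M": [0.2, 0.1, 0.5]},
        index=["a", "b", "c"],
    )
    assert rs.select_dominated_samples(frac, ["E1", "E2"]) == ["a", "b"]
    assert rs.select_dominated_samples(frac, ["M"], min_fraction=0.5) == ["c"]


def test_slope_ftest_detects_trend():
    import pandas as pd

    flat = rs.EnrichmentProfile(pd.DataFrame(
        dict(substitution="C>A", bin=list("1234"),
             observed=1, expected=1,
             enrichment=[1.0, 1.01, 0.99, 1.0], boot_sd=0.01)
    ))
    steep = rs.EnrichmentProfile(pd.DataFrame(
        dict(substitution="C>A", bin=list("1234"),
             observed=1, expected=1,
             enrichment=[0.8, 0.95, 1.05, 1.2], boot_sd=0.01)
    ))
    assert rs.slope_ftest(flat, "C>A") > 0.3
    assert rs.slope_ftest(steep, "C>A") < 0.05


# --- strand asymmetry ---


def _asym_cohort(seed, strand_bias=None, n_samples=6):
    cfg = rs.CohortConfig(
        n_samples=n_samples, seed=seed, genotype_mix={"POLE-MSS": 1.0},
        burden_range={"POLE-MSS": (2000, 4000)},
        genotype_signature_weights={"POLE-MSS": {"E": 0.8, "B": 0.2}},
        strand_bias=strand_bias, reference_length=1_000_000,
    )
    return rs.generate_cohort(cfg)


def test_strand_asymmetry_two_to_one_bias():
    coh = _asym_cohort(41, strand_bias={"C>A": 2.0})
    opp = rs.stranded_opportunities(coh.reference, coh.strand_track)
    prof = rs.strand_asymmetry(
        coh.mutations, list(coh.annotations["sample"]), opp, n_boot=300, seed=0
    )
    row = prof.table.loc["C>A"]
    assert abs(row["log2_ratio"] - 1.0) <= 3 * row["log2_sd"]


def test_strand_asymmetry_symmetric_null():
    coh = _asym_cohort(42)
    opp = rs.stranded_opportunities(coh.reference, coh.strand_track)
    prof = rs.strand_asymmetry(
        coh.mutations, list(coh.annotations["sample"]), opp, n_boot=300, seed=0
    )
    for sub in ("C>A", "C>T"):  # the signature's dominant types
        row = prof.table.loc[sub]
        assert abs(row["log2_ratio"]) <= 3 * row["log2_sd"]


def test_strand_label_swap_negates_ratios(small_cohort):
    opp = rs.stranded_opportunities(
        small_cohort.reference, small_cohort.strand_track
    )
    # symmetric opportunities are required for exact antisymmetry
    opp["lagging"] = opp["leading"] = (opp["leading"] + opp["lagging"]) // 2
    samples = list(small_cohort.annotations["sample"])
    a = rs.strand_asymmetry(small_cohort.mutations, samples, opp, n_boot=5, seed=0)
    swapped = small_cohort.mutations.copy()
    swapped["strand_label"] = swapped["strand_label"].map(
        {"leading": "lagging", "lagging": "leading"}
    )
    b = rs.strand_asymmetry(swapped, samples, opp, n_boot=5, seed=0)
    ra, rb = a.table["log2_ratio"], b.table["log2_ratio"]
    ok = ra.notna() & rb.notna()
    assert np.allclose(ra[ok], -rb[ok])


def test_stranded_densities_recount(small_cohort):
    opp = rs.stranded_opportunities(
        small_cohort.reference, small_cohort.strand_track
    )
    samples = list(small_cohort.annotations["sample"])
    prof = rs.strand_asymmetry(small_cohort.mutations, samples, opp, n_boot=5, seed=0)
    t = prof.table
    total = (t["leading_count"] + t["lagging_count"]).sum()
    n_stranded = small_cohort.mutations["strand_label"].notna().sum()
    assert total == n_stranded
    # density x opportunity returns the counts
    assert np.allclose(
        t["leading_density"] * opp["leading"].to_numpy(), t["leading_count"]
    )
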