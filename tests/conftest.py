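import warnings

import pytest

import replisig as rs

# degenerate-model warnings (uniform probabilities on unseen channels) are
# expected when driving downstream stages from sparse truth models
warnings.filterwarnings(
    "ignore", message="channels unseen under all signatures*"
)


RECOVERY_GENOTYPES = {
    "POLE-MSS": {"E": 0.9, "M": 0.1},
    "MSI": {"M": 0.9, "E": 0.1},
    "POLE-MSI": {"C": 0.8, "E": 0.1, "M": 0.1},
}


def recovery_config(seed: int = 7, n_samples: int = 60) -> rs.CohortConfig:
    """Three well-separated truth signatures, mixed genotypes, burdens
    spanning 500-20,000 — the parameter-recovery study condition."""
    truth = {
        k: v for k, v in rs.default_truth_signatures(seed).items()
        if k in ("E", "M", "C")
    }
    return rs.CohortConfig(
        n_samples=n_samples,
        seed=seed,
        truth_signatures=truth,
        genotype_mix={g: 1 / 3 for g in RECOVERY_GENOTYPES},
        burden_range={g: (500, 20_000) for g in RECOVERY_GENOTYPES},
        genotype_signature_weights=RECOVERY_GENOTYPES,
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    return rs.generate_cohort(recovery_config())


@pytest.fixture(scope="session")
def recovery_catalog(recovery_cohort):
    return rs.build_catalog(recovery_cohort.mutations)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-genotype cohort exercising every record field."""
    cfg = rs.CohortConfig(
        n_samples=8,
        seed=5,
        burden_range={
            g: (200, 800)
            for g in ("POLE-MSS", "POLE-MSI", "POLD1-MSI", "MSI", "MSS", "POLD1-MSS")
        },
    )
    return rs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def reference_table():
    return rs.ReferenceSignatureTable.synthetic(n=30, seed=1)
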