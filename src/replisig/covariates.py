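"""Replication-timing enrichment and replicative strand asymmetry.

Replication timing: the reference is partitioned into timing bins (four
quartiles by default).  For each substitution type S and bin, the observed
mutation count of selected patients is compared with the expected count
under a flat mutation rate,

    n_exp(p, S, bin) = sum_{c in S} lambda(c, p) / N_global(c) * N_bin(c),

where N(c) counts mutable positions (opportunities) for channel c and
lambda(c, p) = sum_i W[c, i] H[i, p] is patient p's model-attributed
burden on channel c.  Summed over bins the expected counts recover the
attributed burden exactly.  Observed and expected are summed over patients
before taking the ratio; error bars come from resampling patients with
replacement.

Strand asymmetry: mutational densities are computed with respect to the
leading-strand template for the 12 stranded substitution classes — the six
pyrimidine substitution types split by whether the A or C of the mutated
base pair lies on the leading or the lagging template — each normalized by
the corresponding stranded opportunity count.  Asymmetries are the log2
ratios of complementary classes; error bars come from resampling mutations
with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .channels import (
    BASES,
    N_SNV_CHANNELS,
    SUBSTITUTION_LABELS,
)
from .extraction import SignatureModel

STRAND_LABELS = ("leading", "lagging")


# ---------------------------------------------------------------------------
# Opportunities

@dataclass
class OpportunityTrack:
    """Per-channel mutable-position counts, genome-wide and per timing bin.

    All six substitution types at a given pentamer context share one
    opportunity count; values are expanded to the 1536 SNV channels."""

    global_counts: np.ndarray          # (1536,)
    bin_counts: np.ndarray             # (n_bins, 1536)
    bin_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.global_counts < 0).any() or (self.bin_counts < 0).any():
            raise ValueError("opportunity counts must be non-negative")
        if not np.array_equal(self.bin_counts.sum(axis=0), self.global_counts):
            raise ValueError("bin opportunities must sum to the global counts")


def count_opportunities(seq: str, timing_track: pd.DataFrame) -> OpportunityTrack:
    """Opportunity counts from a reference sequence and timing intervals."""
    bins = timing_track["bin"].tolist()
    per_bin = np.zeros((len(bins), N_SNV_CHANNELS), dtype=np.int64)
    for k, (start, end) in enumerate(
        zip(timing_track["start"], timing_track["end"])
    ):
        counts = _bin_context_counts(seq, int(start), int(end))
        per_bin[k] = _expand_to_channels(counts)
    glob = per_bin.sum(axis=0)
    return OpportunityTrack(glob, per_bin, tuple(bins))


def _bin_context_counts(seq: str, lo: int, hi: int) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    c = lut[codes]
    pos = np.arange(max(lo, 2), min(hi, len(c) - 2))
    out = np.zeros((2, 256), dtype=np.int64)
    if len(pos) == 0:
        return out
    center = c[pos]
    is_pyr = (center == 1) | (center == 3)
    comp = 3 - c
    ctx_fwd = c[pos - 2] * 64 + c[pos - 1] * 16 + c[pos + 1] * 4 + c[pos + 2]
    ctx_rev = comp[pos + 2] * 64 + comp[pos + 1] * 16 + comp[pos - 1] * 4 + comp[pos - 2]
    ctx = np.where(is_pyr, ctx_fwd, ctx_rev)
    center_pyr = np.where(is_pyr, center, 3 - center)
    np.add.at(out, ((center_pyr == 3).astype(int), ctx), 1)
    return out


def _expand_to_channels(counts_2x256: np.ndarray) -> np.ndarray:
    """Expand (center, context) counts to the 1536 channels (three
    substitution types per center share one count)."""
    out = np.empty(N_SNV_CHANNELS, dtype=np.int64)
    for sub in range(6):
        center = 0 if sub < 3 else 1
        out[sub * 256:(sub + 1) * 256] = counts_2x256[center]
    return out


# ---------------------------------------------------------------------------
# Expected counts

def lambda_channel_burden(model: SignatureModel, sample: str | int) -> np.ndarray:
    """Per-channel attributed burden lambda(c, p) = sum_i W[c,i] H[i,p]."""
    p = (
        sample if isinstance(sample, (int, np.integer))
        else model.sample_labels.index(sample)
    )
    return model.W @ model.H[:, p]


def _sub_slice(sub_label: str) -> slice:
    s = SUBSTITUTION_LABELS.index(sub_label)
    return slice(s * 256, (s + 1) * 256)


def expected_bin_count(
    lam: np.ndarray,
    opportunities: OpportunityTrack,
    substitution: str,
    bin_label: str,
) -> float:
    """The flat-rate expected count of one (substitution, bin) cell."""
    sl = _sub_slice(substitution)
    lam_s = np.asarray(lam[: N_SNV_CHANNELS])[sl]
    n_glob = opportunities.global_counts[sl].astype(float)
    k = opportunities.bin_labels.index(bin_label)
    n_bin = opportunities.bin_counts[k][sl].astype(float)
    bad = (n_glob == 0) & (lam_s > 0)
    if bad.any():
        raise ValueError(
            "positive burden on channels with zero global opportunity; "
            "reference and catalog are inconsistent"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(n_glob > 0, lam_s / n_glob * n_bin, 0.0)
    return float(contrib.sum())


# ---------------------------------------------------------------------------
# Timing profiles

@dataclass
class EnrichmentProfile:
    """Observed/expected mutation density per (substitution, timing bin)."""

    table: pd.DataFrame  # columns: substitution, bin, observed, expected,
    #                      enrichment, boot_sd

    def cell(self, substitution: str, bin_label: str) -> pd.Series:
        t = self.table
        return t[(t["substitution"] == substitution) & (t["bin"] == bin_label)].iloc[0]


def _per_patient_arrays(
    mutations: pd.DataFrame,
    samples: Sequence[str],
    model: SignatureModel,
    opportunities: OpportunityTrack,
    substitutions: Sequence[str],
):
    bins = list(opportunities.bin_labels)
    n_p, n_s, n_b = len(samples), len(substitutions), len(bins)
    obs = np.zeros((n_p, n_s, n_b))
    exp = np.zeros((n_p, n_s, n_b))
    snv = mutations[
        (mutations["variant_class"] == "SNV")
        & mutations["sample"].isin(samples)
    ]
    sub_of_channel = snv["channel"].to_numpy() // 256
    for i_p, s in enumerate(samples):
        mask_p = snv["sample"].to_numpy() == s
        lam = lambda_channel_burden(model, s)
        for i_s, sub in enumerate(substitutions):
            sub_idx = SUBSTITUTION_LABELS.index(sub)
            mask = mask_p & (sub_of_channel == sub_idx)
            tb = snv["timing_bin"].to_numpy()[mask]
            for i_b, b in enumerate(bins):
                obs[i_p, i_s, i_b] = (tb == b).sum()
                exp[i_p, i_s, i_b] = expected_bin_count(
                    lam, opportunities, sub, b
                )
    return obs, exp, bins


def timing_profile(
    mutations: pd.DataFrame,
    samples: Sequence[str],
    model: SignatureModel,
    opportunities: OpportunityTrack,
    substitutions: Sequence[str] = ("C>A", "C>T"),
    n_boot: int = 1000,
    seed: int = 0,
) -> EnrichmentProfile:
    """Observed/expected enrichment per timing bin, aggregated over the
    selected patients (ratio of sums), with patient-bootstrap SDs.

    Under a flat mutation rate every enrichment is 1 in expectation; cells
    with no observed mutations of the substitution type are flagged by a
    NaN enrichment when the expected count is zero as well.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples selected")
    obs, exp, bins = _per_patient_arrays(
        mutations, samples, model, opportunities, substitutions
    )
    obs_tot = obs.sum(axis=0)
    exp_tot = exp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        enrich = np.where(exp_tot > 0, obs_tot / exp_tot, np.nan)
    sd = bootstrap_patients(obs, exp, n_boot=n_boot, seed=seed)
    rows = []
    for i_s, sub in enumerate(substitutions):
        for i_b, b in enumerate(bins):
            rows.append(
                dict(
                    substitution=sub, bin=b,
                    observed=obs_tot[i_s, i_b], expected=exp_tot[i_s, i_b],
                    enrichment=enrich[i_s, i_b], boot_sd=sd[i_s, i_b],
                )
            )
    return EnrichmentProfile(pd.DataFrame(rows))


def bootstrap_patients(
    obs: np.ndarray, exp: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> np.ndarray:
    """SD of the ratio-of-sums enrichment under patient resampling.

    ``obs`` and ``exp`` are (patients, ...) arrays of per-patient observed
    and expected counts; patients are drawn with replacement ``n_boot``
    times and the elementwise SD of the recomputed enrichment returned.
    A single patient yields SD 0 in every cell."""
    rng = np.random.default_rng(seed)
    n_p = obs.shape[0]
    if n_p < 1:
        raise ValueError("need at least one patient")
    idx = rng.integers(0, n_p, size=(n_boot, n_p))
    reps = np.empty((n_boot,) + obs.shape[1:])
    for r in range(n_boot):
        o = obs[idx[r]].sum(axis=0)
        e = exp[idx[r]].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            reps[r] = np.where(e > 0, o / e, np.nan)
    return np.nanstd(reps, axis=0)


def select_dominated_samples(
    activity_fractions: pd.DataFrame,
    group_signatures: Sequence[str],
    min_fraction: float = 0.75,
) -> list[str]:
    """Samples whose spectra are dominated by a signature group.

    ``activity_fractions`` is a samples x signatures table of fractions
    (rows summing to 1); a sample qualifies when the group's summed
    fraction is at least ``min_fraction``."""
    cols = [s for s in group_signatures if s in activity_fractions.columns]
    frac = activity_fractions[cols].sum(axis=1)
    return list(activity_fractions.index[frac >= min_fraction])


def slope_ftest(profile: EnrichmentProfile, substitution: str) -> float:
    """F-test p-value for a non-zero linear trend of enrichment across the
    ordered timing bins (utility for synthetic profiles)."""
    t = profile.table
    y = t.loc[t["substitution"] == substitution, "enrichment"].to_numpy()
    x = np.arange(len(y), dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.f_pvalue)


# ---------------------------------------------------------------------------
# Strand asymmetry

def stranded_opportunities(seq: str, strand_track: pd.DataFrame) -> pd.DataFrame:
    """Opportunity counts for the 12 stranded classes.

    For each substitution type the relevant count is the number of
    positions whose A-or-C base (the C itself for C-centered types, the A
    complementary to the T for T-centered types) lies on the leading
    (resp. lagging) strand template."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    c = lut[codes]
    pos = np.arange(2, len(c) - 2)
    ends = strand_track["end"].to_numpy()
    fwd_lead = strand_track["fwd_is_leading"].to_numpy()[
        np.searchsorted(ends, pos, side="right")
    ]
    center = c[pos]
    counts = {}
    for base_code, base in ((0, "A"), (1, "C")):
        on_fwd = center == base_code
        on_rev = center == (3 - base_code)
        lead = (on_fwd & fwd_lead) | (on_rev & ~fwd_lead)
        lag = (on_fwd & ~fwd_lead) | (on_rev & fwd_lead)
        counts[base] = (int(lead.sum()), int(lag.sum()))
    rows = []
    for sub in SUBSTITUTION_LABELS:
        base = "C" if sub.startswith("C") else "A"
        lead, lag = counts[base]
        rows.append(dict(substitution=sub, leading=lead, lagging=lag))
    return pd.DataFrame(rows).set_index("substitution")


@dataclass
class AsymmetryProfile:
    """12 stranded densities, 6 log2(leading/lagging) ratios, bootstrap SDs."""

    table: pd.DataFrame  # per substitution: counts, densities, log2 ratio, SDs


def strand_asymmetry(
    mutations: pd.DataFrame,
    samples: Iterable[str],
    opportunities: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> AsymmetryProfile:
    """Leading/lagging stranded densities and log2 asymmetries.

    Densities are mutation counts per stranded opportunity; the log2 ratio
    is flagged NaN when either strand has zero density (no pseudo-count).
    SDs come from resampling mutations with replacement, opportunities held
    fixed."""
    rng = np.random.default_rng(seed)
    snv = mutations[
        (mutations["variant_class"] == "SNV")
        & mutations["sample"].isin(list(samples))
        & mutations["strand_label"].notna()
    ]
    sub_idx = snv["channel"].to_numpy() // 256
    is_lead = snv["strand_label"].to_numpy() == "leading"
    counts = np.zeros((6, 2), dtype=np.int64)
    np.add.at(counts, (sub_idx, (~is_lead).astype(int)), 1)

    opp = np.stack(
        [
            opportunities.loc[list(SUBSTITUTION_LABELS), "leading"].to_numpy(),
            opportunities.loc[list(SUBSTITUTION_LABELS), "lagging"].to_numpy(),
        ],
        axis=1,
    ).astype(float)

    def densities(cnt: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(opp > 0, cnt / opp, np.nan)

    dens = densities(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2r = np.where(
            (dens[:, 0] > 0) & (dens[:, 1] > 0),
            np.log2(dens[:, 0] / dens[:, 1]),
            np.nan,
        )

    # mutation bootstrap == multinomial resampling of the 12-cell counts
    total = counts.sum()
    reps_log2 = np.full((n_boot, 6), np.nan)
    if total > 0:
        p = counts.ravel() / total
        draws = rng.multinomial(total, p, size=n_boot).reshape(n_boot, 6, 2)
        for r in range(n_boot):
            d = densities(draws[r])
            with np.errstate(invalid="ignore", divide="ignore"):
                reps_log2[r] = np.where(
                    (d[:, 0] > 0) & (d[:, 1] > 0),
                    np.log2(d[:, 0] / d[:, 1]),
                    np.nan,
                )
    sd = np.nanstd(reps_log2, axis=0)
    table = pd.DataFrame(
        dict(
            substitution=list(SUBSTITUTION_LABELS),
            leading_count=counts[:, 0], lagging_count=counts[:, 1],
            leading_density=dens[:, 0], lagging_density=dens[:, 1],
            log2_ratio=log2r, log2_sd=sd,
        )
    ).set_index("substitution")
    return AsymmetryProfile(table)
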