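"""Synthetic tumor cohorts with known mutational-process ground truth.

The generator emulates the structure of an exome cohort containing
polymerase-proofreading-deficient (POLE/POLD1-exo*), mismatch-repair-
deficient (MSI) and doubly deficient tumors: per-sample mutation burdens
spanning two to five orders of magnitude, mutation catalogs drawn from
genotype-specific mixtures of ground-truth signatures over the 1536+8
channel space, microsatellite-indel burdens tied to MSI status, cancer-
cell-fraction (CCF) estimates with clonal and subclonal populations, and
replication-timing / replication-strand annotations derived from toy
reference tracks.

Ground-truth signatures are synthesized as sparse peaked vectors (a few
dominant pentamer channels around fixed trimer motifs) rather than copied
from an external database; they are well separated by construction, which
is what makes parameter-recovery testing of the downstream extraction
meaningful.  An ``order_scenario`` knob controls whether one repair defect
precedes the other: under ``pole_first`` a configurable fraction of each
doubly deficient sample's burden is emitted from the single-defect
signature with clonal CCFs only, emulating mutations accumulated before
the second event.

All coordinates are 0-based half-open in memory; writers emit 1-based
inclusive positions in the MAF-like dialect.  A single integer seed drives
every stochastic draw.
"""

from __future__ import annotations

import json
import textwrap
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    CHANNEL_SPACE,
    COMPLEMENT,
    N_CHANNELS,
    N_SNV_CHANNELS,
    SUBSTITUTIONS,
    SUBSTITUTION_LABELS,
    encode_trimer_channel,
)
from .catalog import write_maf

GENOTYPES = ("POLE-MSS", "POLE-MSI", "POLD1-MSI", "MSI", "MSS", "POLD1-MSS")
ORDER_SCENARIOS = ("simultaneous", "pole_first", "msi_first")

_BASE_CODES = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# Ground-truth signatures

def _peaked_signature(
    rng: np.random.Generator,
    anchors: list[tuple[str, str]],
    indel_mass: dict[str, float] | None = None,
    background_mass: float = 0.08,
    peaks_per_anchor: int = 4,
) -> np.ndarray:
    """A sparse 1544-channel signature peaked at pentamer channels around
    the given (trimer, alt) anchor motifs, with a thin random background."""
    vec = np.zeros(N_CHANNELS)
    indel_mass = indel_mass or {}
    peak_mass = 1.0 - background_mass - sum(indel_mass.values())
    share = peak_mass / len(anchors)
    for trimer, alt in anchors:
        tri = encode_trimer_channel(trimer, alt)
        # the 16 pentamer preimages of this trimer channel
        pre = np.flatnonzero(CHANNEL_SPACE.collapse_map == tri)
        chosen = rng.choice(pre, size=peaks_per_anchor, replace=False)
        w = rng.dirichlet(np.full(peaks_per_anchor, 1.5)) * share
        vec[chosen] += w
    bg = rng.choice(N_SNV_CHANNELS, size=40, replace=False)
    vec[bg] += background_mass / 40
    labels = {lab: N_SNV_CHANNELS + i for i, lab in enumerate(CHANNEL_SPACE.indel_channels)}
    for lab, mass in indel_mass.items():
        vec[labels[lab]] += mass
    return vec / vec.sum()


def _broad_signature(rng: np.random.Generator, n_channels: int = 300) -> np.ndarray:
    """A flat-ish background signature spread over many SNV channels."""
    vec = np.zeros(N_CHANNELS)
    chosen = rng.choice(N_SNV_CHANNELS, size=n_channels, replace=False)
    vec[chosen] = rng.dirichlet(np.full(n_channels, 5.0))
    return vec


def default_truth_signatures(seed: int = 0) -> dict[str, np.ndarray]:
    """Five well-separated truth signatures over the 1544-channel space.

    E emulates a proofreading-deficiency process (T[C>A]T / T[C>T]G peaks),
    M a mismatch-repair-deficiency process (CpG C>T plus 1-bp indels), C and
    D concurrent-deficiency processes with distinct motifs (including the
    G[C>A]T peak characteristic of combined loss), and B a broad background.
    """
    rng = np.random.default_rng(seed)
    return {
        "E": _peaked_signature(rng, [("TCT", "A"), ("TCG", "T")]),
        "M": _peaked_signature(
            rng, [("ACG", "T"), ("CCG", "T"), ("GCG", "T")],
            indel_mass={"DEL1": 0.10, "INS1": 0.05},
        ),
        "C": _peaked_signature(
            rng, [("GCT", "A"), ("TCT", "G"), ("ATA", "C")],
            indel_mass={"DEL1": 0.04},
        ),
        "D": _peaked_signature(
            rng, [("CCT", "T"), ("TTT", "C")], indel_mass={"DEL1": 0.06}
        ),
        "B": _broad_signature(rng),
    }


# ---------------------------------------------------------------------------
# Configuration

def _default_mix() -> dict[str, float]:
    return {
        "POLE-MSS": 0.10, "POLE-MSI": 0.15, "POLD1-MSI": 0.10,
        "MSI": 0.25, "MSS": 0.35, "POLD1-MSS": 0.05,
    }


def _default_burdens() -> dict[str, tuple[int, int]]:
    return {
        "MSS": (100, 1_000), "POLD1-MSS": (100, 2_000),
        "MSI": (1_000, 10_000), "POLD1-MSI": (2_000, 20_000),
        "POLE-MSS": (5_000, 100_000), "POLE-MSI": (10_000, 100_000),
    }


def _default_ms_indel_rates() -> dict[str, float]:
    return {
        "MSS": 5.0, "POLD1-MSS": 5.0, "MSI": 300.0,
        "POLD1-MSI": 300.0, "POLE-MSS": 10.0, "POLE-MSI": 250.0,
    }


def _default_weights() -> dict[str, dict[str, float]]:
    return {
        "MSS": {"B": 1.0},
        "POLD1-MSS": {"B": 1.0},
        "POLE-MSS": {"E": 0.85, "B": 0.15},
        "MSI": {"M": 0.85, "B": 0.15},
        "POLE-MSI": {"C": 0.80, "M": 0.10, "E": 0.10},
        "POLD1-MSI": {"D": 0.70, "M": 0.30},
    }


@dataclass
class CohortConfig:
    """Fully specifies one synthetic cohort; every draw flows from ``seed``."""

    n_samples: int = 60
    genotype_mix: dict[str, float] = field(default_factory=_default_mix)
    burden_range: dict[str, tuple[int, int]] = field(default_factory=_default_burdens)
    ms_indel_rate: dict[str, float] = field(default_factory=_default_ms_indel_rates)
    truth_signatures: dict[str, np.ndarray] | None = None
    genotype_signature_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_weights
    )
    clonal_fraction: float = 0.8
    ccf_noise_sd: float = 0.03
    order_scenario: str = "simultaneous"
    clonal_first_fraction: float = 0.3
    timing_bias: dict[str, float] | None = None
    strand_bias: dict[str, float] | None = None
    reference_length: int = 20_000
    n_timing_bins: int = 4
    seed: int = 0

    def resolved_signatures(self) -> dict[str, np.ndarray]:
        if self.truth_signatures is None:
            return default_truth_signatures(self.seed)
        return self.truth_signatures

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        total = sum(self.genotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype fractions sum to {total}, not 1")
        sigs = self.resolved_signatures()
        if not sigs:
            raise ValueError("truth signature set is empty")
        for name, vec in sigs.items():
            vec = np.asarray(vec)
            if vec.shape != (N_CHANNELS,):
                raise ValueError(f"signature {name!r} is not a {N_CHANNELS}-vector")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-8:
                raise ValueError(f"signature {name!r} must be non-negative, sum 1")
        for g, (lo, hi) in self.burden_range.items():
            if lo > hi:
                raise ValueError(f"burden min > max for {g}")
        if self.order_scenario not in ORDER_SCENARIOS:
            raise ValueError(f"unknown order_scenario {self.order_scenario!r}")
        if not 0.0 <= self.clonal_fraction <= 1.0:
            raise ValueError("clonal_fraction must lie in [0, 1]")
        for g, w in self.genotype_signature_weights.items():
            for s in w:
                if s not in sigs:
                    raise ValueError(f"genotype {g} refers to unknown signature {s!r}")


@dataclass
class SyntheticCohort:
    """A generated cohort: mutation table, annotations, reference tracks
    and the ground truth that produced them."""

    mutations: pd.DataFrame
    annotations: pd.DataFrame
    reference: str
    timing_track: pd.DataFrame
    strand_track: pd.DataFrame
    truth_signatures: dict[str, np.ndarray]
    truth_exposures: pd.DataFrame  # signatures x samples, realized counts
    config: CohortConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_maf(self.mutations, outdir / "mutations.maf.tsv")
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        with open(outdir / "reference.fa", "w") as fh:
            fh.write(">chr1\n")
            fh.write(textwrap.fill(self.reference, 60) + "\n")
        t = self.timing_track.copy()
        t.insert(0, "chrom", "chr1")
        t.to_csv(outdir / "timing.bed", sep="\t", index=False, header=False)
        s = self.strand_track.copy()
        s["strand"] = np.where(s.pop("fwd_is_leading"), "+", "-")
        s.insert(0, "chrom", "chr1")
        s.to_csv(outdir / "strand.bed", sep="\t", index=False, header=False)
        truth = {
            "config": {
                k: v for k, v in asdict(self.config).items()
                if k != "truth_signatures"
            },
            "signatures": {k: v.tolist() for k, v in self.truth_signatures.items()},
            "exposures": self.truth_exposures.to_dict(),
        }
        (outdir / "truth.json").write_text(json.dumps(truth))


# ---------------------------------------------------------------------------
# Reference tracks

def generate_reference_tracks(
    length: int, n_bins: int = 4, seed: int = 0
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Random reference sequence plus timing-quartile and replication-strand
    interval tracks.

    Timing bins Q1..Qn (Qn latest) partition [0, length); each timing bin is
    split into two halves of opposite replication-fork orientation, the
    ``fwd_is_leading`` flag saying whether the forward strand serves as the
    leading-strand template there.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if length < 5 * n_bins:
        raise ValueError("length must be at least 5 x n_bins")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    seq = "".join(BASES[c] for c in codes)
    bounds = np.linspace(0, length, n_bins + 1).astype(int)
    timing = pd.DataFrame(
        {
            "start": bounds[:-1],
            "end": bounds[1:],
            "bin": [f"Q{i + 1}" for i in range(n_bins)],
        }
    )
    rows = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        mid = (start + end) // 2
        rows.append((start, mid, True))
        rows.append((mid, end, False))
    strand = pd.DataFrame(rows, columns=["start", "end", "fwd_is_leading"])
    return seq, timing, strand


# ---------------------------------------------------------------------------
# Position index

class _PositionIndex:
    """Per-context candidate positions of a reference, with timing bin and
    strand-orientation annotations, grouped for O(1) lookup.

    Group key = center_base_index * 256 + flank_context_index, where
    center_base_index is 0 for pyrimidine-C positions and 1 for T.
    """

    def __init__(self, seq: str, timing: pd.DataFrame, strand: pd.DataFrame):
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.int64)
        for b, i in _BASE_CODES.items():
            lut[ord(b)] = i
        c = lut[codes]
        L = len(c)
        pos = np.arange(2, L - 2)
        center = c[pos]
        is_pyr = (center == 1) | (center == 3)
        comp = 3 - c
        ctx_fwd = c[pos - 2] * 64 + c[pos - 1] * 16 + c[pos + 1] * 4 + c[pos + 2]
        ctx_rev = comp[pos + 2] * 64 + comp[pos + 1] * 16 + comp[pos - 1] * 4 + comp[pos - 2]
        ctx = np.where(is_pyr, ctx_fwd, ctx_rev)
        center_pyr = np.where(is_pyr, center, 3 - center)  # 1 (C) or 3 (T)
        center_idx = (center_pyr == 3).astype(np.int64)
        key = center_idx * 256 + ctx
        self.timing_ends = timing["end"].to_numpy()
        tb = np.searchsorted(self.timing_ends, pos, side="right")
        self.bin_labels = timing["bin"].to_numpy()
        fwd_lead_bounds = strand["end"].to_numpy()
        si = np.searchsorted(fwd_lead_bounds, pos, side="right")
        fwd_lead = strand["fwd_is_leading"].to_numpy()[si]
        order = np.argsort(key, kind="stable")
        self.pos = pos[order]
        self.pyr_plus = is_pyr[order]
        self.bin_idx = tb[order]
        self.fwd_lead = fwd_lead[order]
        self.starts = np.searchsorted(key[order], np.arange(513))

    def group(self, center_is_c: bool, ctx: int):
        k = (0 if center_is_c else 1) * 256 + ctx
        lo, hi = self.starts[k], self.starts[k + 1]
        return slice(lo, hi)


# ---------------------------------------------------------------------------
# Cohort generation

def _allocate_genotypes(mix: dict[str, float], n: int, rng) -> np.ndarray:
    """Largest-remainder allocation of n samples to genotype fractions."""
    names = list(mix)
    raw = np.array([mix[g] for g in names]) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:rem]] += 1
    labels = np.repeat(names, counts)
    return rng.permutation(labels)


def _draw_ccfs(rng, n: int, clonal: np.ndarray, noise_sd: float):
    ccf = np.empty(n)
    half = np.empty(n)
    nc = int(clonal.sum())
    ccf[clonal] = np.clip(rng.normal(0.95, 0.03, size=nc), 0, 1)
    half[clonal] = np.abs(rng.normal(0.08, noise_sd, size=nc))
    ns = n - nc
    ccf[~clonal] = rng.uniform(0.1, 0.5, size=ns)
    half[~clonal] = 0.1 + np.abs(rng.normal(0.0, noise_sd, size=ns))
    lo = np.clip(ccf - half, 0.0, 1.0)
    hi = np.clip(ccf + half, 0.0, 1.0)
    return ccf, lo, hi


_MUT_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "variant_class", "context5",
    "indel_len", "ccf", "ccf_lo", "ccf_hi", "timing_bin", "strand_label",
    "channel", "truth_signature",
]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from its configuration.

    Mutations are drawn channel-wise from each sample's genotype signature
    mixture and placed at reference positions carrying the channel's
    pentamer context (on either strand).  Fixed seed implies byte-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigs = config.resolved_signatures()
    sig_names = list(sigs)
    sig_matrix = {k: np.asarray(v, dtype=float) for k, v in sigs.items()}

    seq, timing, strand = generate_reference_tracks(
        config.reference_length, config.n_timing_bins, seed=config.seed
    )
    index = _PositionIndex(seq, timing, strand)
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    timing_mult = None
    if config.timing_bias:
        timing_mult = np.array(
            [config.timing_bias.get(b, 1.0) for b in index.bin_labels]
        )

    genotypes = _allocate_genotypes(config.genotype_mix, config.n_samples, rng)
    samples = [f"S{i:03d}" for i in range(config.n_samples)]

    chunks: list[dict] = []
    exposures = np.zeros((len(sig_names), config.n_samples))
    total_snv = np.zeros(config.n_samples, dtype=int)

    for j, (sample, genotype) in enumerate(zip(samples, genotypes)):
        lo, hi = config.burden_range[genotype]
        burden = int(rng.integers(lo, hi + 1))
        weights = config.genotype_signature_weights[genotype]
        wnames = list(weights)
        wvals = np.array([weights[s] for s in wnames], dtype=float)
        wvals = wvals / wvals.sum()

        draws: list[tuple[str, np.ndarray, bool]] = []  # (sig, counts, clonal_only)
        if genotype == "POLE-MSI" and config.order_scenario != "simultaneous":
            first = "E" if config.order_scenario == "pole_first" else "M"
            if first not in sig_matrix:
                raise ValueError(
                    f"order_scenario {config.order_scenario!r} needs a "
                    f"{first!r} truth signature"
                )
            n_first = int(round(config.clonal_first_fraction * burden))
            draws.append(
                (first, rng.multinomial(n_first, sig_matrix[first]), True)
            )
            rest_totals = rng.multinomial(burden - n_first, wvals)
            exposures[sig_names.index(first), j] += n_first
        else:
            rest_totals = rng.multinomial(burden, wvals)
        for name, n_i in zip(wnames, rest_totals):
            if n_i > 0:
                draws.append((name, rng.multinomial(n_i, sig_matrix[name]), False))
                exposures[sig_names.index(name), j] += n_i

        for sig_name, counts, clonal_only in draws:
            for ch in np.flatnonzero(counts):
                n = int(counts[ch])
                chunks.append(
                    _emit_channel(
                        rng, index, seq, seq_arr, config, timing_mult,
                        sample, sig_name, int(ch), n, clonal_only,
                    )
                )

    if chunks:
        mutations = pd.concat(
            [pd.DataFrame(c) for c in chunks], ignore_index=True
        )
    else:
        mutations = pd.DataFrame(columns=_MUT_COLUMNS)

    # per-sample CCFs need a single pass so clonal_fraction applies per mutation
    if len(mutations):
        clonal = mutations.pop("_clonal_only").to_numpy(dtype=bool)
        free = ~clonal
        clonal[free] = rng.random(int(free.sum())) < config.clonal_fraction
        ccf, lo, hi = _draw_ccfs(rng, len(mutations), clonal, config.ccf_noise_sd)
        mutations["ccf"], mutations["ccf_lo"], mutations["ccf_hi"] = ccf, lo, hi
        mutations = mutations[_MUT_COLUMNS]
        snv_counts = (
            mutations[mutations["variant_class"] == "SNV"]
            .groupby("sample").size()
        )
        for j, s in enumerate(samples):
            total_snv[j] = int(snv_counts.get(s, 0))

    annotations = _build_annotations(rng, samples, genotypes, config, total_snv)
    exposures_df = pd.DataFrame(exposures, index=sig_names, columns=samples)
    return SyntheticCohort(
        mutations=mutations,
        annotations=annotations,
        reference=seq,
        timing_track=timing,
        strand_track=strand,
        truth_signatures=sig_matrix,
        truth_exposures=exposures_df,
        config=config,
    )


def _emit_channel(
    rng, index: _PositionIndex, seq: str, seq_arr: np.ndarray,
    config: CohortConfig, timing_mult, sample: str, sig_name: str,
    channel: int, n: int, clonal_only: bool,
) -> dict:
    out: dict = {
        "sample": np.repeat(sample, n), "chrom": np.repeat("chr1", n),
        "channel": np.full(n, channel), "truth_signature": np.repeat(sig_name, n),
        "_clonal_only": np.repeat(clonal_only, n),
        "ccf": np.full(n, np.nan), "ccf_lo": np.full(n, np.nan),
        "ccf_hi": np.full(n, np.nan),
    }
    if channel < N_SNV_CHANNELS:
        sub = channel // 256
        ctx = channel % 256
        ref_pyr, alt_pyr = SUBSTITUTIONS[sub]
        sl = index.group(ref_pyr == "C", ctx)
        cands_pos = index.pos[sl]
        if len(cands_pos) == 0:
            raise ValueError(
                f"reference lacks any position with the context of channel "
                f"{CHANNEL_SPACE.snv_channels[channel]}; use a longer reference"
            )
        pyr_plus = index.pyr_plus[sl]
        fwd_lead = index.fwd_lead[sl]
        bin_idx = index.bin_idx[sl]
        # A-or-C base strand: the C itself for C-centered channels, the
        # complementary A (opposite strand) for T-centered channels
        ac_plus = pyr_plus if ref_pyr == "C" else ~pyr_plus
        leading = ac_plus == fwd_lead
        w = np.ones(len(cands_pos))
        if timing_mult is not None:
            w *= timing_mult[bin_idx]
        if config.strand_bias:
            ratio = config.strand_bias.get(SUBSTITUTION_LABELS[sub])
            if ratio is not None:
                w *= np.where(leading, ratio, 1.0)
        if len(cands_pos) == 1:
            chosen = np.zeros(n, dtype=int)
        else:
            chosen = rng.choice(len(cands_pos), size=n, p=w / w.sum())
        pos = cands_pos[chosen]
        plus = pyr_plus[chosen]
        out["pos"] = pos
        out["ref"] = np.where(plus, ref_pyr, COMPLEMENT[ref_pyr])
        out["alt"] = np.where(plus, alt_pyr, COMPLEMENT[alt_pyr])
        out["variant_class"] = np.repeat("SNV", n)
        out["context5"] = [
            seq[p - 2: p + 3] for p in pos
        ]
        out["indel_len"] = np.full(n, np.nan)
        out["timing_bin"] = index.bin_labels[bin_idx[chosen]]
        out["strand_label"] = np.where(leading[chosen], "leading", "lagging")
    else:
        k = channel - N_SNV_CHANNELS
        is_ins = k < 4
        size = k % 4 + 1
        lens = (
            np.full(n, size) if size < 4
            else rng.integers(4, 7, size=n)
        )
        L = len(seq)
        pos = rng.integers(2, L - 8, size=n)
        refs, alts = [], []
        for p, ln in zip(pos, lens):
            if is_ins:
                refs.append("-")
                alts.append("".join(BASES[b] for b in rng.integers(0, 4, ln)))
            else:
                refs.append(seq[p: p + ln])
                alts.append("-")
        out["pos"] = pos
        out["ref"] = refs
        out["alt"] = alts
        out["variant_class"] = np.repeat("INS" if is_ins else "DEL", n)
        out["context5"] = np.repeat(None, n)
        out["indel_len"] = lens.astype(float)
        bi = np.searchsorted(index.timing_ends, pos, side="right")
        out["timing_bin"] = index.bin_labels[np.clip(bi, 0, len(index.bin_labels) - 1)]
        out["strand_label"] = np.repeat(None, n)
    return out


def _build_annotations(
    rng, samples, genotypes, config: CohortConfig, total_snv
) -> pd.DataFrame:
    rows = []
    for j, (s, g) in enumerate(zip(samples, genotypes)):
        msi = "MSI-H" if g.endswith("MSI") else "MSS"
        pole = "WT"
        pold1 = "WT"
        if g.startswith("POLE"):
            pole = rng.choice(["P286R", "V411L", "exo*"], p=[0.5, 0.2, 0.3])
        if g.startswith("POLD1"):
            pold1 = "exo*"
        mlh1 = bool(rng.random() < 0.7) if msi == "MSI-H" else False
        ms_indels = int(rng.poisson(config.ms_indel_rate.get(g, 0.0)))
        rows.append(
            dict(
                sample=s, genotype=g, pole_exo_status=pole,
                pold1_exo_status=pold1, msi_status=msi, mlh1_silenced=mlh1,
                ms_indel_count=ms_indels, total_snv=int(total_snv[j]),
            )
        )
    cols = [
        "sample", "genotype", "pole_exo_status", "pold1_exo_status",
        "msi_status", "mlh1_silenced", "ms_indel_count", "total_snv",
    ]
    return pd.DataFrame(rows, columns=cols)
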