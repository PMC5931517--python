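"""Mutation tables and channel count matrices.

Mutations live in a MAF-like tab-delimited dialect with columns
``sample, chrom, pos, ref, alt, variant_class, context5, ccf, ccf_lo,
ccf_hi`` (plus optional ``indel_len, timing_bin, strand_label``).  On disk
positions are 1-based inclusive; in memory they are 0-based half-open.
``build_catalog`` tallies records into a channels x samples count matrix
over the 1536 SNV + 8 indel channel space; records that cannot be
channelized (N bases, missing indel length, out-of-range context) are
excluded and counted in a QC report rather than failing the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .channels import (
    CHANNEL_SPACE,
    N_CHANNELS,
    N_SNV_CHANNELS,
    ChannelEncodingError,
    encode_indel_channel,
    encode_snv_channel,
)

MAF_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "variant_class",
    "context5", "indel_len", "ccf", "ccf_lo", "ccf_hi",
    "timing_bin", "strand_label",
]


@dataclass
class MutationRecord:
    """One somatic variant with context, clonality and genomic annotations."""

    sample: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    variant_class: str  # "SNV", "INS" or "DEL"
    pentamer: str | None = None
    indel_len: int | None = None
    ccf: float = np.nan
    ccf_lo: float = np.nan
    ccf_hi: float = np.nan
    timing_bin: str | None = None
    strand_label: str | None = None


@dataclass
class CatalogMatrix:
    """Non-negative channels x samples count matrix."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    sample_labels: tuple[str, ...]
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.channel_labels), len(self.sample_labels)):
            raise ValueError("values shape does not match labels")
        if (self.values < 0).any():
            raise ValueError("catalog counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.channel_labels),
            columns=list(self.sample_labels),
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def read(cls, path: str | Path) -> "CatalogMatrix":
        df = pd.read_csv(path, sep="\t", index_col="channel")
        return cls(df.to_numpy(), tuple(df.index), tuple(df.columns))


def extract_pentamer(sequence: str, pos: int) -> str:
    """Reference bases [pos-2, pos+2] on the forward strand (0-based pos)."""
    if pos < 2 or pos > len(sequence) - 3:
        raise ChannelEncodingError(
            f"position {pos} is within 2 bases of the sequence end"
        )
    return str(sequence[pos - 2: pos + 3]).upper()


def encode_record_channel(
    variant_class: str,
    pentamer: str | None,
    alt: str | None,
    indel_len: float | None,
) -> int:
    """Channel index of one record; raises ChannelEncodingError when invalid."""
    if variant_class == "SNV":
        if pentamer is None or not isinstance(pentamer, str):
            raise ChannelEncodingError("SNV lacks a pentamer context")
        return encode_snv_channel(pentamer, alt)
    if variant_class in ("INS", "DEL"):
        if indel_len is None or (isinstance(indel_len, float) and np.isnan(indel_len)):
            raise ChannelEncodingError("indel lacks a length")
        return encode_indel_channel(int(indel_len), variant_class == "INS")
    raise ChannelEncodingError(f"unknown variant class {variant_class!r}")


def _as_frame(mutations) -> pd.DataFrame:
    if isinstance(mutations, pd.DataFrame):
        return mutations
    rows = []
    for rec in mutations:
        rows.append(
            dict(
                sample=rec.sample, chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alt=rec.alt, variant_class=rec.variant_class,
                context5=rec.pentamer, indel_len=rec.indel_len, ccf=rec.ccf,
                ccf_lo=rec.ccf_lo, ccf_hi=rec.ccf_hi,
                timing_bin=rec.timing_bin, strand_label=rec.strand_label,
            )
        )
    return pd.DataFrame(rows, columns=MAF_COLUMNS)


def encode_channels(mutations: pd.DataFrame | Iterable[MutationRecord]) -> tuple[pd.Series, dict]:
    """Per-record channel indices (-1 where excluded) plus QC counts."""
    df = _as_frame(mutations)
    idx = np.full(len(df), -1, dtype=np.intp)
    qc: dict[str, int] = {}
    ctx = df["context5"].to_numpy(dtype=object) if "context5" in df else np.full(len(df), None)
    ilen = df["indel_len"].to_numpy() if "indel_len" in df else np.full(len(df), np.nan)
    for i, (vc, pent, alt, ln) in enumerate(
        zip(df["variant_class"], ctx, df["alt"], ilen)
    ):
        try:
            idx[i] = encode_record_channel(vc, pent, alt, ln)
        except ChannelEncodingError as err:
            key = str(err).split(",")[0][:60]
            qc[key] = qc.get(key, 0) + 1
    return pd.Series(idx, index=df.index, name="channel"), qc


def build_catalog(
    mutations: pd.DataFrame | Iterable[MutationRecord],
    include_indels: bool = True,
    samples: Iterable[str] | None = None,
) -> CatalogMatrix:
    """Tally mutations into a (1544 or 1536) x samples count matrix.

    ``samples`` may declare the column order (and zero-count samples);
    otherwise samples appear in first-occurrence order.
    """
    df = _as_frame(mutations)
    if "channel" in df.columns:
        channel = df["channel"]
        qc: dict = {"precomputed_channels": True}
    else:
        channel, qc = encode_channels(df)
    if samples is None:
        samples = list(dict.fromkeys(df["sample"])) if len(df) else []
    samples = list(samples)
    n_rows = N_CHANNELS if include_indels else N_SNV_CHANNELS
    values = np.zeros((n_rows, len(samples)), dtype=np.int64)
    sample_pos = {s: j for j, s in enumerate(samples)}
    ok = channel.to_numpy() >= 0
    if not include_indels:
        ok &= channel.to_numpy() < N_SNV_CHANNELS
    if ok.any():
        rows = channel.to_numpy()[ok]
        cols = np.array([sample_pos[s] for s in df["sample"].to_numpy()[ok]])
        np.add.at(values, (rows, cols), 1)
    labels = CHANNEL_SPACE.all_channels if include_indels else CHANNEL_SPACE.snv_channels
    qc["n_input"] = int(len(df))
    qc["n_encoded"] = int(ok.sum())
    return CatalogMatrix(values, labels, tuple(samples), qc=qc)


def annotate_pentamers(df: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Fill the context5 column of SNV rows from a reference sequence."""
    df = df.copy()
    ctx = []
    for vc, pos in zip(df["variant_class"], df["pos"]):
        if vc != "SNV":
            ctx.append(None)
            continue
        try:
            ctx.append(extract_pentamer(reference, int(pos)))
        except ChannelEncodingError:
            ctx.append(None)
    df["context5"] = ctx
    return df


def read_fasta(path: str | Path, contig: str | None = None) -> str:
    """Load one contig's sequence from a FASTA file (first contig by
    default)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    name = contig if contig is not None else list(fa.keys())[0]
    return str(fa[name][:])


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read the MAF-like dialect; converts positions to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    """Write the MAF-like dialect; emits 1-based inclusive positions."""
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    cols = [c for c in MAF_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def write_qc(qc: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(qc), indent=2, default=int))
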