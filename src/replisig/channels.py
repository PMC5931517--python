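"""Mutation channel spaces.

Single-nucleotide variants are classified into 1536 channels: six
pyrimidine-centered substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 256 pentanucleotide contexts formed by the two bases on
either side of the mutated base.  Small insertions and deletions occupy
eight further channels by size class (1, 2, 3, >=4 bases).  The
conventional 96-channel trinucleotide space is obtained by collapsing
pentamer channels that share a trimer motif.

Channel ordering is fixed and documented: substitution types in the order
above, contexts lexicographic by the (-2, -1, +1, +2) flanking bases, and
the eight indel channels appended after the SNV block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")

#: Substitution types in fixed order, pyrimidine-centered.
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)
SUBSTITUTION_LABELS: tuple[str, ...] = tuple(f"{r}>{a}" for r, a in SUBSTITUTIONS)
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

INDEL_CHANNELS: tuple[str, ...] = (
    "INS1", "INS2", "INS3", "INS4+", "DEL1", "DEL2", "DEL3", "DEL4+",
)

N_SNV_CHANNELS = 1536
N_INDEL_CHANNELS = 8
N_CHANNELS = N_SNV_CHANNELS + N_INDEL_CHANNELS
N_TRIMER_CHANNELS = 96


class ChannelEncodingError(ValueError):
    """Raised for records that cannot be channelized (N bases, bad alleles)."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def encode_snv_channel(pentamer: str, alt: str) -> int:
    """Channel index in [0, 1536) of a SNV given its 5-base reference context.

    Purine-centered inputs are reverse-complemented so the stored channel is
    pyrimidine-centered; the two strand descriptions of one mutation map to
    the same channel.
    """
    if len(pentamer) != 5:
        raise ChannelEncodingError(f"pentamer must have 5 bases, got {pentamer!r}")
    pentamer = pentamer.upper()
    alt = alt.upper()
    if any(b not in _BASE_INDEX for b in pentamer) or alt not in _BASE_INDEX:
        raise ChannelEncodingError(f"ambiguous base in {pentamer!r}>{alt!r}")
    if pentamer[2] not in PYRIMIDINES:
        pentamer = reverse_complement(pentamer)
        alt = COMPLEMENT[alt]
    ref = pentamer[2]
    if alt == ref:
        raise ChannelEncodingError(f"alt equals reference base {ref!r}")
    sub = _SUB_INDEX[(ref, alt)]
    m2, m1, _, p1, p2 = pentamer
    ctx = (
        _BASE_INDEX[m2] * 64 + _BASE_INDEX[m1] * 16
        + _BASE_INDEX[p1] * 4 + _BASE_INDEX[p2]
    )
    return sub * 256 + ctx


def encode_indel_channel(indel_len: int, is_insertion: bool) -> int:
    """Index in [1536, 1544): lengths 1-3 own a channel, >=4 share one."""
    if indel_len < 1:
        raise ChannelEncodingError(f"indel length must be >= 1, got {indel_len}")
    size = min(indel_len, 4) - 1
    return N_SNV_CHANNELS + (0 if is_insertion else 4) + size


def encode_trimer_channel(trimer: str, alt: str) -> int:
    """Channel index in [0, 96) for the collapsed trinucleotide space."""
    if len(trimer) != 3:
        raise ChannelEncodingError(f"trimer must have 3 bases, got {trimer!r}")
    trimer = trimer.upper()
    alt = alt.upper()
    if any(b not in _BASE_INDEX for b in trimer) or alt not in _BASE_INDEX:
        raise ChannelEncodingError(f"ambiguous base in {trimer!r}>{alt!r}")
    if trimer[1] not in PYRIMIDINES:
        trimer = reverse_complement(trimer)
        alt = COMPLEMENT[alt]
    sub = _SUB_INDEX[(trimer[1], alt)]
    return sub * 16 + _BASE_INDEX[trimer[0]] * 4 + _BASE_INDEX[trimer[2]]


def _snv_labels() -> list[str]:
    labels = []
    for ref, alt in SUBSTITUTIONS:
        for m2 in BASES:
            for m1 in BASES:
                for p1 in BASES:
                    for p2 in BASES:
                        labels.append(f"{m2}{m1}[{ref}>{alt}]{p1}{p2}")
    return labels


def _trimer_labels() -> list[str]:
    labels = []
    for ref, alt in SUBSTITUTIONS:
        for m1 in BASES:
            for p1 in BASES:
                labels.append(f"{m1}[{ref}>{alt}]{p1}")
    return labels


@dataclass(frozen=True)
class ChannelSpace:
    """The fixed 1536+8 channel catalog space and its 96-channel projection."""

    snv_channels: tuple[str, ...] = field(default_factory=lambda: tuple(_snv_labels()))
    indel_channels: tuple[str, ...] = INDEL_CHANNELS
    trimer_channels: tuple[str, ...] = field(default_factory=lambda: tuple(_trimer_labels()))

    @property
    def all_channels(self) -> tuple[str, ...]:
        return self.snv_channels + self.indel_channels

    @property
    def collapse_map(self) -> np.ndarray:
        """Integer array of length 1536: pentamer channel -> trimer channel."""
        idx = np.empty(N_SNV_CHANNELS, dtype=np.intp)
        for sub in range(6):
            for ctx in range(256):
                m1 = (ctx // 16) % 4
                p1 = (ctx // 4) % 4
                idx[sub * 256 + ctx] = sub * 16 + m1 * 4 + p1
        return idx

    def substitution_of_snv_channel(self, channel: int) -> str:
        """Substitution-type label ('C>A' ... 'T>G') of a pentamer channel."""
        if not 0 <= channel < N_SNV_CHANNELS:
            raise IndexError(f"not a SNV channel: {channel}")
        return SUBSTITUTION_LABELS[channel // 256]

    def context_of_snv_channel(self, channel: int) -> int:
        """Pentamer-context index in [0, 256) of a SNV channel."""
        if not 0 <= channel < N_SNV_CHANNELS:
            raise IndexError(f"not a SNV channel: {channel}")
        return channel % 256


#: Shared immutable instance; the space never varies.
CHANNEL_SPACE = ChannelSpace()


def collapse_to_trimer(values: np.ndarray, drop_indels: bool = True) -> np.ndarray:
    """Project 1536- (or 1544-) channel vectors/matrices to 96 channels.

    Each trimer channel receives the sum of its 16 pentamer preimages; indel
    rows, if present, are dropped.  Works on 1-D vectors or (channels x n)
    matrices; total SNV mass is conserved.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    if values.shape[0] == N_CHANNELS:
        if not drop_indels:
            raise ValueError("input has indel rows; pass drop_indels=True")
        values = values[:N_SNV_CHANNELS]
    elif values.shape[0] != N_SNV_CHANNELS:
        raise ValueError(
            f"expected {N_SNV_CHANNELS} or {N_CHANNELS} channel rows, "
            f"got {values.shape[0]}"
        )
    out = np.zeros((N_TRIMER_CHANNELS, values.shape[1]))
    np.add.at(out, CHANNEL_SPACE.collapse_map, values)
    return out[:, 0] if squeeze else out


def context_index_of_pentamer(pentamer: str) -> int:
    """Index in [0, 256) of a pyrimidine-centered pentamer's flanking bases."""
    pentamer = pentamer.upper()
    if pentamer[2] not in PYRIMIDINES:
        pentamer = reverse_complement(pentamer)
    m2, m1, _, p1, p2 = pentamer
    return (
        _BASE_INDEX[m2] * 64 + _BASE_INDEX[m1] * 16
        + _BASE_INDEX[p1] * 4 + _BASE_INDEX[p2]
    )
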