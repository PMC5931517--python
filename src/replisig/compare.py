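"""Comparison of discovered signatures against a reference database.

Signatures are compared in the 96-channel trinucleotide space by cosine
similarity.  A two-component match fits non-negative coefficients
(alpha1, alpha2) maximizing the cosine of alpha1*C1 + alpha2*C2 with a
target profile; only the ratio alpha1:alpha2 is meaningful.  Two false-
discovery backgrounds are provided: the distribution of best matches over
all signature pairs against the (exclusion-filtered) reference set, and a
channel-shuffling permutation null in which each signature's 96 values are
permuted — preserving its sparsity — before fitting, repeated for many
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .channels import N_TRIMER_CHANNELS, collapse_to_trimer

_EPS = 1e-15


@dataclass
class ReferenceSignatureTable:
    """Named 96-channel reference profiles, each normalized to sum 1."""

    names: list[str]
    profiles: np.ndarray  # 96 x n

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (N_TRIMER_CHANNELS, len(self.names)):
            raise ValueError("profiles must be 96 x len(names)")
        if (self.profiles < 0).any():
            raise ValueError("reference profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("reference profiles must be non-zero")
        self.profiles = self.profiles / sums

    @classmethod
    def read(cls, path: str | Path) -> "ReferenceSignatureTable":
        """Read a COSMIC-layout TSV: a context column plus one column per
        signature.  Row order is taken as given."""
        df = pd.read_csv(path, sep="\t")
        ctx_col = df.columns[0]
        df = df.drop(columns=[ctx_col])
        return cls(list(df.columns), df.to_numpy())

    def write(self, path: str | Path, channel_labels: Iterable[str]) -> None:
        out = pd.DataFrame(self.profiles, columns=self.names)
        out.insert(0, "context", list(channel_labels))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def synthetic(cls, n: int = 30, seed: int = 0, n_peaks: int = 5) -> "ReferenceSignatureTable":
        """A synthetic stand-in reference of peaked 96-channel profiles, for
        tests and demonstrations (no external signature database is bundled)."""
        rng = np.random.default_rng(seed)
        profiles = np.zeros((N_TRIMER_CHANNELS, n))
        for j in range(n):
            peaks = rng.choice(N_TRIMER_CHANNELS, size=n_peaks, replace=False)
            profiles[peaks, j] = rng.dirichlet(np.ones(n_peaks)) * 0.9
            bg = rng.choice(N_TRIMER_CHANNELS, size=20, replace=False)
            profiles[bg, j] += 0.1 / 20
        return cls([f"REF{j + 1}" for j in range(n)], profiles)


@dataclass
class CombinationFit:
    alpha: tuple[float, float]
    cosine: float
    target_name: str | None = None


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative, non-zero 96-vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(a @ b / (na * nb))


def as_96(vec: np.ndarray) -> np.ndarray:
    """Accept a 96-, 1536- or 1544-channel vector; collapse when needed."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] == N_TRIMER_CHANNELS:
        return vec
    return collapse_to_trimer(vec)


def fit_combination(
    c1: np.ndarray, c2: np.ndarray, target: np.ndarray,
    target_name: str | None = None, grid: int = 201,
) -> CombinationFit:
    """Non-negative two-signature combination maximizing cosine to target.

    Solved as a 1-D maximization over the mixing fraction t = a1/(a1+a2) on
    [0, 1]: a coarse grid locates the basin, then bounded scalar
    optimization refines it.  Returned alphas are normalized to sum 1.
    """
    c1, c2, target = as_96(c1), as_96(c2), as_96(target)
    if np.linalg.norm(target) == 0:
        raise ValueError("target is a zero vector")

    def neg_cos(t: float) -> float:
        mix = t * c1 + (1 - t) * c2
        n = np.linalg.norm(mix)
        if n == 0:
            return 0.0
        return -float(mix @ target) / (n * np.linalg.norm(target))

    ts = np.linspace(0.0, 1.0, grid)
    vals = np.array([neg_cos(t) for t in ts])
    i = int(vals.argmin())
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, grid - 1)]
    res = minimize_scalar(neg_cos, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    best_t, best = (float(res.x), -float(res.fun))
    if -vals[i] > best:
        best_t, best = float(ts[i]), -float(vals[i])
    return CombinationFit(alpha=(best_t, 1.0 - best_t), cosine=best,
                          target_name=target_name)


def _best_combo_cosines(c1: np.ndarray, c2: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Exact closed-form best combination cosine of the pair (c1, c2)
    against every column of R (96 x m), vectorized.

    Maximizing (alpha.g) / sqrt(alpha.G.alpha) over alpha >= 0 with
    g = [c1.s, c2.s] and G the pair's Gram matrix has solution
    alpha* = G^-1 g when interior (both components non-negative), else the
    better single signature.
    """
    R = R / (np.linalg.norm(R, axis=0, keepdims=True) + _EPS)
    g11 = float(c1 @ c1)
    g22 = float(c2 @ c2)
    g12 = float(c1 @ c2)
    det = g11 * g22 - g12 * g12
    b1 = c1 @ R  # (m,)
    b2 = c2 @ R
    single = np.maximum(b1 / np.sqrt(g11), b2 / np.sqrt(g22))
    if det <= _EPS:  # collinear pair
        return np.clip(single, 0.0, 1.0)
    a1 = (g22 * b1 - g12 * b2) / det
    a2 = (g11 * b2 - g12 * b1) / det
    interior = (a1 >= 0) & (a2 >= 0)
    qf = b1 * a1 + b2 * a2  # g' G^-1 g >= 0
    combo = np.sqrt(np.maximum(qf, 0.0))
    return np.clip(np.where(interior, combo, single), 0.0, 1.0)


def pairwise_background(
    signatures: Mapping[str, np.ndarray],
    reference: ReferenceSignatureTable,
    exclusions: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Best combination-fit cosine of every unordered signature pair against
    the reference set, honoring per-signature exclusion lists of known
    true-positive matches."""
    names = list(signatures)
    if len(names) < 2:
        raise ValueError("need at least two signatures")
    exclusions = {k: set(v) for k, v in (exclusions or {}).items()}
    vecs = {k: as_96(v) for k, v in signatures.items()}
    rows = []
    for i, s1 in enumerate(names):
        for s2 in names[i + 1:]:
            banned = exclusions.get(s1, set()) | exclusions.get(s2, set())
            keep = [j for j, r in enumerate(reference.names) if r not in banned]
            if not keep:
                raise ValueError(f"no reference left for pair ({s1}, {s2})")
            R = reference.profiles[:, keep]
            cos = _best_combo_cosines(vecs[s1], vecs[s2], R)
            j = int(cos.argmax())
            rows.append(
                dict(sig1=s1, sig2=s2, best_reference=reference.names[keep[j]],
                     cosine=float(cos[j]))
            )
    return pd.DataFrame(rows)


def permutation_null(
    signatures: Mapping[str, np.ndarray],
    reference: ReferenceSignatureTable,
    n_perm: int = 10_000,
    seed: int = 0,
    threshold: float = 0.99,
) -> tuple[np.ndarray, float]:
    """Channel-shuffle permutation null of the pairwise best-match cosine.

    Each iteration independently permutes every signature's 96 channel
    values (preserving its sorted value multiset, hence its sparsity), fits
    all pairs against the full reference and records the best cosine.
    Returns the null distribution and the empirical P(best >= threshold).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(signatures)
    vecs = [as_96(signatures[k]) for k in names]
    R = reference.profiles
    out = np.empty(n_perm)
    k = len(vecs)
    for it in range(n_perm):
        shuffled = [v[rng.permutation(N_TRIMER_CHANNELS)] for v in vecs]
        best = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                best = max(
                    best,
                    float(_best_combo_cosines(shuffled[i], shuffled[j], R).max()),
                )
        out[it] = best
    return out, float((out >= threshold).mean())
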