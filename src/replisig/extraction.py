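"""Signature discovery by Bayesian NMF with automatic relevance determination.

The catalog V (channels x samples) is factorized as V ~ Poisson(W H) by
multiplicative updates minimizing the KL divergence, with exponential
(L1-type) priors on each component's column of W and row of H whose rate
hyperparameters are updated in closed form.  Components whose relevance
collapses are pruned at convergence, so the effective number of signatures
K_effective is inferred rather than fixed.  Multiple independent runs are
summarized by a consensus rule: the modal K_effective wins, ties broken by
the lowest final objective.

After fitting, W columns are normalized to sum to one (signature profiles)
and H carries the magnitudes (mutations attributed per signature per
sample); the product W.H is invariant under this renormalization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .catalog import CatalogMatrix

_EPS = 1e-12


@dataclass
class SignatureModel:
    """Fitted factor pair: profiles W (columns sum 1) and activities H."""

    W: np.ndarray  # channels x K
    H: np.ndarray  # K x samples
    channel_labels: tuple[str, ...]
    sample_labels: tuple[str, ...]
    signature_names: tuple[str, ...]
    K_effective: int
    objective_trace: list[float] = field(default_factory=list)
    run_seed: int = 0
    n_iter: int = 0

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.W, index=list(self.channel_labels),
            columns=list(self.signature_names),
        ).to_csv(outdir / "W.tsv", sep="\t", index_label="channel")
        pd.DataFrame(
            self.H, index=list(self.signature_names),
            columns=list(self.sample_labels),
        ).to_csv(outdir / "H.tsv", sep="\t", index_label="signature")


@dataclass
class ConsensusReport:
    runs: list[dict]          # per run: seed, K_effective, final objective
    chosen_run: int
    K_histogram: dict[int, int]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "runs": self.runs,
                    "chosen_run": self.chosen_run,
                    "K_histogram": {str(k): v for k, v in self.K_histogram.items()},
                },
                indent=2,
            )
        )


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    return float(
        (V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum()
    )


def bayes_nmf(
    catalog: CatalogMatrix | np.ndarray,
    K_max: int = 20,
    max_iter: int = 100_000,
    tol: float = 1e-7,
    seed: int = 0,
    a: float = 10.0,
    prune_relevance: float = 1e-8,
    check_every: int = 10,
) -> SignatureModel:
    """One ARD-NMF run.

    Parameters
    ----------
    K_max : upper bound on the number of components; clamped (with a
        warning) to min(channels, samples).
    a : shape hyperparameter of the inverse-gamma hyperprior on the
        per-component relevance; the scale ``b`` is set from the data mean
        so the prior matches the catalog's magnitude.
    prune_relevance : components whose mass falls below this fraction of
        the largest component's mass at convergence are pruned.

    The MAP objective (KL divergence plus prior terms) is non-increasing
    across iterations up to numerical tolerance; the trace is recorded
    every ``check_every`` iterations.
    """
    if isinstance(catalog, CatalogMatrix):
        V = np.asarray(catalog.values, dtype=float)
        channel_labels = catalog.channel_labels
        sample_labels = catalog.sample_labels
    else:
        V = np.asarray(catalog, dtype=float)
        channel_labels = tuple(f"ch{i}" for i in range(V.shape[0]))
        sample_labels = tuple(f"s{j}" for j in range(V.shape[1]))
    if (V < 0).any():
        raise ValueError("catalog must be non-negative")
    if V.sum() == 0:
        raise ValueError("catalog is all zero")
    F, P = V.shape
    K = int(K_max)
    if K < 1:
        raise ValueError("K_max must be >= 1")
    if K > min(F, P):
        warnings.warn(
            f"K_max={K} exceeds min(dim)={min(F, P)}; clamping", stacklevel=2
        )
        K = min(F, P)

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / K)
    W = rng.random((F, K)) * scale + _EPS
    H = rng.random((K, P)) * scale + _EPS
    b = np.sqrt((a - 1) * (a - 2) * V.mean() / K)
    denom_lam = F + P + a + 1

    lam = (W.sum(axis=0) + H.sum(axis=1) + b) / denom_lam

    def objective() -> float:
        WH = W @ H + _EPS
        kl = _kl_divergence(V, WH)
        prior = (
            ((W.sum(axis=0) + H.sum(axis=1)) / lam).sum()
            + denom_lam * np.log(lam).sum()
            + (b / lam).sum()
        )
        return kl + prior

    trace = [objective()]
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + 1.0 / lam[:, None] + _EPS)
        H += _EPS
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + 1.0 / lam[None, :] + _EPS)
        W += _EPS
        lam = (W.sum(axis=0) + H.sum(axis=1) + b) / denom_lam
        if it % check_every == 0:
            obj = objective()
            prev = trace[-1]
            trace.append(obj)
            if abs(prev - obj) <= tol * abs(prev):
                break

    mass = W.sum(axis=0) * H.sum(axis=1)
    keep = mass > prune_relevance * mass.max()
    W, H = W[:, keep], H[keep]
    colsum = W.sum(axis=0)
    W = W / colsum
    H = H * colsum[:, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order]
    K_eff = int(keep.sum())
    names = tuple(f"S{i + 1}" for i in range(K_eff))
    return SignatureModel(
        W=W, H=H, channel_labels=channel_labels, sample_labels=sample_labels,
        signature_names=names, K_effective=K_eff, objective_trace=trace,
        run_seed=seed, n_iter=n_iter,
    )


def consensus(
    catalog: CatalogMatrix | np.ndarray,
    n_runs: int = 10,
    seeds: list[int] | None = None,
    **nmf_kwargs,
) -> tuple[ConsensusReport, SignatureModel]:
    """Run independent fits and choose the modal-K, lowest-objective one."""
    if seeds is None:
        base = int(nmf_kwargs.pop("seed", 0))
        seeds = [base + i for i in range(n_runs)]
    if len(seeds) < 1:
        raise ValueError("need at least one run")
    models = [bayes_nmf(catalog, seed=s, **nmf_kwargs) for s in seeds]
    hist: dict[int, int] = {}
    for m in models:
        hist[m.K_effective] = hist.get(m.K_effective, 0) + 1
    top = max(hist.values())
    modal_ks = {k for k, v in hist.items() if v == top}
    candidates = [i for i, m in enumerate(models) if m.K_effective in modal_ks]
    chosen = min(candidates, key=lambda i: models[i].final_objective)
    report = ConsensusReport(
        runs=[
            {
                "seed": m.run_seed,
                "K_effective": m.K_effective,
                "final_objective": m.final_objective,
            }
            for m in models
        ],
        chosen_run=chosen,
        K_histogram=dict(sorted(hist.items())),
    )
    return report, models[chosen]


def signature_probability_matrix(
    model: SignatureModel, sample: str | int
) -> np.ndarray:
    """P(signature i | channel c, sample p) as a (K x channels) matrix.

    Channels unseen under every signature for this sample get a uniform
    vector (with a warning the first time).
    """
    p = (
        sample if isinstance(sample, (int, np.integer))
        else model.sample_labels.index(sample)
    )
    h = model.H[:, p]
    if not h.any():
        raise ValueError(f"sample {sample!r} has all-zero activities")
    joint = model.W * h[None, :]          # channels x K
    denom = joint.sum(axis=1)
    out = np.empty_like(joint.T)
    zero = denom <= 0
    if zero.any():
        warnings.warn(
            "channels unseen under all signatures assigned uniform "
            "probabilities", stacklevel=2
        )
        out[:, zero] = 1.0 / model.W.shape[1]
    nz = ~zero
    out[:, nz] = (joint[nz] / denom[nz, None]).T
    return out


def mutation_signature_probabilities(
    model: SignatureModel, channel: int, sample: str | int
) -> np.ndarray:
    """Probability vector over signatures for one (channel, sample) pair."""
    return signature_probability_matrix(model, sample)[:, channel]


def activity_fractions(model: SignatureModel) -> pd.DataFrame:
    """Per-sample signature fractions h_ip / sum_j h_jp (rows sum to 1);
    zero-burden samples yield all-NaN rows."""
    totals = model.H.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, model.H / totals, np.nan)
    return pd.DataFrame(
        frac.T, index=list(model.sample_labels),
        columns=list(model.signature_names),
    )


def cosine_match(
    W: np.ndarray, truth: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Optimal one-to-one assignment of fitted columns to truth signatures
    maximizing total cosine similarity (for recovery harnesses)."""
    names = list(truth)
    T = np.stack([np.asarray(truth[n], dtype=float) for n in names], axis=1)
    Wn = W / (np.linalg.norm(W, axis=0, keepdims=True) + _EPS)
    Tn = T / (np.linalg.norm(T, axis=0, keepdims=True) + _EPS)
    C = Wn.T @ Tn  # fitted x truth
    rows, cols = linear_sum_assignment(-C)
    return pd.DataFrame(
        {
            "truth": [names[c] for c in cols],
            "fitted": [int(r) for r in rows],
            "cosine": [float(C[r, c]) for r, c in zip(rows, cols)],
        }
    )


def model_from_truth(cohort) -> SignatureModel:
    """A SignatureModel built directly from a synthetic cohort's ground
    truth (truth profiles as W, realized exposures as H).  Used to exercise
    downstream stages independently of NMF fitting quality."""
    sig_names = tuple(cohort.truth_signatures)
    W = np.stack([cohort.truth_signatures[n] for n in sig_names], axis=1)
    H = cohort.truth_exposures.loc[list(sig_names)].to_numpy(dtype=float)
    from .channels import CHANNEL_SPACE

    return SignatureModel(
        W=W, H=H,
        channel_labels=CHANNEL_SPACE.all_channels,
        sample_labels=tuple(cohort.truth_exposures.columns),
        signature_names=sig_names,
        K_effective=len(sig_names),
        objective_trace=[np.nan],
    )
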