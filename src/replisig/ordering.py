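"""Ordering of proofreading-loss and mismatch-repair-loss events.

If one repair defect preceded the other, mutations bearing the earlier
defect's single-deficiency signature (E for proofreading loss, M for MMR
loss) should be enriched among a tumor's clonal mutations relative to the
concurrent-deficiency signature C, and depleted among subclonal ones:

    H0:  n_E^c / n_C^c  <=  n_E^s / n_C^s       (likewise for M)

where n^c and n^s are clonal and subclonal mutation masses obtained by
summing per-mutation signature probabilities.  Mutations are called clonal
when the lower bound of their 95% CCF interval exceeds 0.75, subclonal
when the upper bound is below 0.75, and ambiguous (excluded) otherwise.
Significance is assessed by drawing Poisson counts parameterized by the
four masses and counting how often the clonal ratio fails to exceed the
subclonal one; ties count toward the null side (conservative) and draws
with a zero denominator are discarded and redrawn.  Benjamini-Hochberg
correction is applied across patients, both hypotheses in one family,
with significance at q < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .extraction import SignatureModel, signature_probability_matrix

DEFAULT_GROUPS = {"E": ("E",), "M": ("M",), "C": ("C",)}
CLONAL_CCF_BOUND = 0.75


def partition_clonality(mutations: pd.DataFrame) -> pd.Series:
    """Label each mutation clonal / subclonal / ambiguous from its 95% CCF
    interval bounds.  Missing bounds yield ambiguous, with a warning."""
    lo = pd.to_numeric(mutations["ccf_lo"], errors="coerce")
    hi = pd.to_numeric(mutations["ccf_hi"], errors="coerce")
    missing = lo.isna() | hi.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} mutations lack CCF intervals; "
            "labelled ambiguous", stacklevel=2
        )
    labels = np.where(
        lo > CLONAL_CCF_BOUND, "clonal",
        np.where(hi < CLONAL_CCF_BOUND, "subclonal", "ambiguous"),
    )
    labels[missing.to_numpy()] = "ambiguous"
    return pd.Series(labels, index=mutations.index, name="clonality")


def select_candidates(
    activities: pd.DataFrame,
    group_signatures: tuple[str, ...] = ("C",),
    min_mutations: float = 100.0,
    min_fraction: float = 0.35,
) -> list[str]:
    """Samples eligible for the ordering test: the concurrent-signature
    group must contribute at least ``min_mutations`` mutations and at least
    ``min_fraction`` of the total attributed mass (both bounds inclusive).

    ``activities`` is a samples x signatures table of attributed mutation
    counts (e.g. ``model.H.T`` with signature columns)."""
    cols = [c for c in group_signatures if c in activities.columns]
    mass = activities[cols].sum(axis=1)
    total = activities.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mass / total, 0.0)
    ok = (mass >= min_mutations) & (frac >= min_fraction)
    return list(activities.index[ok])


@dataclass
class OrderingInputs:
    """Clonal and subclonal probability masses per signature group."""

    sample: str
    masses: pd.DataFrame  # index: group labels; columns: clonal, subclonal


def group_masses(
    mutations: pd.DataFrame,
    model: SignatureModel,
    groups: dict[str, tuple[str, ...]] = DEFAULT_GROUPS,
    clonality: pd.Series | None = None,
) -> dict[str, OrderingInputs]:
    """Per-sample clonal/subclonal signature-group masses.

    Per-mutation probabilities P(signature | channel, sample) are summed
    within each group (e.g. P(sigM) = P(sigM1) + P(sigM2)) over the clonal
    and subclonal subsets; ambiguous mutations are excluded."""
    if clonality is None:
        clonality = partition_clonality(mutations)
    sig_index = {s: i for i, s in enumerate(model.signature_names)}
    group_rows = {
        g: [sig_index[s] for s in members if s in sig_index]
        for g, members in groups.items()
    }
    out: dict[str, OrderingInputs] = {}
    for sample, df in mutations.groupby("sample", sort=False):
        if sample not in model.sample_labels:
            continue
        prob = signature_probability_matrix(model, sample)  # K x channels
        masses = pd.DataFrame(
            0.0, index=list(groups), columns=["clonal", "subclonal"]
        )
        for comp in ("clonal", "subclonal"):
            sel = df[clonality.loc[df.index] == comp]
            if not len(sel):
                continue
            counts = np.bincount(
                sel["channel"].to_numpy(), minlength=prob.shape[1]
            )
            mass_per_sig = prob @ counts  # (K,)
            for g, rows in group_rows.items():
                masses.loc[g, comp] = float(mass_per_sig[rows].sum())
        out[sample] = OrderingInputs(sample=sample, masses=masses)
    return out


def ordering_pvalue(
    n_target_clonal: float,
    n_c_clonal: float,
    n_target_subclonal: float,
    n_c_subclonal: float,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Poisson-resampling p-value for clonal enrichment of a target
    signature group relative to the concurrent group C.

    Draws independent Poisson counts for the four masses and returns the
    fraction of draws in which the clonal ratio does not exceed the
    subclonal ratio; small p means the target's mutations are clonally
    enriched (target event first).  Zero-denominator draws are discarded
    and redrawn; exact ties count toward the null side."""
    if n_c_clonal <= 0 or n_c_subclonal <= 0:
        raise ValueError(
            "concurrent-signature mass must be positive in both compartments"
        )
    rng = np.random.default_rng(seed)
    null_count = 0
    remaining = n_draws
    while remaining > 0:
        m = remaining
        tc = rng.poisson(n_target_clonal, m)
        cc = rng.poisson(n_c_clonal, m)
        ts = rng.poisson(n_target_subclonal, m)
        cs = rng.poisson(n_c_subclonal, m)
        valid = (cc > 0) & (cs > 0)
        tc, cc, ts, cs = tc[valid], cc[valid], ts[valid], cs[valid]
        # clonal ratio <= subclonal ratio, via integer cross products
        null_count += int((tc * cs <= ts * cc).sum())
        remaining -= int(valid.sum())
    return null_count / n_draws


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OrderingResult:
    table: pd.DataFrame  # per (sample, hypothesis): masses, p, q, significant
    q_threshold: float = 0.1


def run_ordering(
    mutations: pd.DataFrame,
    model: SignatureModel,
    groups: dict[str, tuple[str, ...]] = DEFAULT_GROUPS,
    candidates: list[str] | None = None,
    n_draws: int = 1_000_000,
    seed: int = 0,
    q_threshold: float = 0.1,
) -> OrderingResult:
    """Full ordering test over a cohort.

    Both the E-first and M-first hypotheses are evaluated for every
    eligible sample and corrected together in a single BH family.  Samples
    whose concurrent-group mass is zero in either compartment are reported
    with missing p/q values."""
    if candidates is None:
        acts = pd.DataFrame(
            model.H.T, index=list(model.sample_labels),
            columns=list(model.signature_names),
        )
        grouped = pd.DataFrame(
            {g: acts[[s for s in members if s in acts.columns]].sum(axis=1)
             for g, members in groups.items()}
        )
        grouped["__total__"] = acts.sum(axis=1)
        mass = grouped["C"]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(
                grouped["__total__"] > 0, mass / grouped["__total__"], 0.0
            )
        candidates = list(grouped.index[(mass >= 100) & (frac >= 0.35)])
    inputs = group_masses(
        mutations[mutations["sample"].isin(candidates)], model, groups
    )
    rng = np.random.default_rng(seed)
    rows = []
    for sample in candidates:
        if sample not in inputs:
            continue
        m = inputs[sample].masses
        for target in ("E", "M"):
            if target not in m.index:
                continue
            row = dict(
                sample=sample, hypothesis=f"{target}_first",
                n_target_clonal=m.loc[target, "clonal"],
                n_c_clonal=m.loc["C", "clonal"],
                n_target_subclonal=m.loc[target, "subclonal"],
                n_c_subclonal=m.loc["C", "subclonal"],
            )
            if m.loc["C", "clonal"] > 0 and m.loc["C", "subclonal"] > 0:
                row["p"] = ordering_pvalue(
                    m.loc[target, "clonal"], m.loc["C", "clonal"],
                    m.loc[target, "subclonal"], m.loc["C", "subclonal"],
                    n_draws=n_draws, seed=int(rng.integers(2**31)),
                )
            else:
                row["p"] = np.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = np.nan
        ok = table["p"].notna()
        if ok.any():
            table.loc[ok, "q"] = bh_correct(table.loc[ok, "p"].to_numpy())
        table["significant"] = table["q"] < q_threshold
    return OrderingResult(table=table, q_threshold=q_threshold)
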