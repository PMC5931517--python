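# Methods

`replisig` analyzes somatic mutation catalogs of tumors with deficient
replication repair: loss of polymerase proofreading (missense mutation in
the POLE or POLD1 exonuclease domain), loss of mismatch repair (MMR,
phenotypically microsatellite instability, MSI), or both at once.  This
note documents the models, the synthetic data they are validated on, the
numerical choices, and the limitations.

## Mutation channels

SNVs are classified by substitution type and pentanucleotide context:
six pyrimidine-centered substitutions (C>A, C>G, C>T, T>A, T>C, T>G) ×
256 flanking contexts at positions −2, −1, +1, +2, giving 1536 channels.
Purine-centered descriptions are reverse-complemented before encoding, so
a mutation and its opposite-strand description land in one channel.  The
expanded context (vs. the conventional 96 trinucleotide channels) helps
separate processes whose 96-channel spectra are similar — exactly the
situation with the different POLE hotspot processes — and is affordable
in hypermutated cohorts where per-channel counts stay informative.  Small
insertions/deletions add eight channels by size class (INS1–3, INS4+,
DEL1–3, DEL4+), which carry most of the MSI phenotype's discriminating
signal.  Channel ordering is fixed: substitutions in the order above,
contexts lexicographic in the four flanking bases, indel channels
appended.  Projection to 96 channels sums the 16 pentamer preimages of
each trimer motif and drops indels; SNV mass is conserved exactly.

Records that cannot be encoded (N bases, indels without a length, complex
substitutions) are excluded and tallied in a QC report rather than
aborting a run.  Microsatellite-locus calling for indels is out of scope;
all input indels are counted by size, and a per-sample microsatellite-
indel count is consumed as an annotation where present.

## Signature discovery: ARD Bayesian NMF

The catalog V (channels × samples) is modeled as V ~ Poisson(WH) and
factorized by multiplicative updates minimizing the KL divergence,
penalized by exponential (L1-type) priors on each component k's column
w_k and row h_k with a shared relevance rate λ_k.  The λ_k carry an
inverse-gamma hyperprior (shape a = 10; scale b set from the data mean so
the prior matches the catalog's magnitude) and are updated in closed
form:

    λ_k = (‖w_k‖₁ + ‖h_k‖₁ + b) / (F + P + a + 1)

with F channels and P samples.  Irrelevant components' λ_k collapse,
driving their mass to ~0; at convergence, components whose mass
(‖w_k‖₁·‖h_k‖₁) falls below 1e−8 of the largest component's are pruned,
so the effective rank K is inferred (automatic relevance determination)
rather than fixed.  The MAP objective is non-increasing across
iterations: the multiplicative updates are monotone at fixed λ and the λ
update is an exact minimizer.  Convergence is declared when the relative
objective change over 10 iterations falls below 1e−7 (cap 100,000
iterations).  After fitting, W columns are normalized to sum one
(signature profiles) with magnitudes absorbed into H (attributed
mutations per signature per sample); W·H is invariant under this
renormalization.

Because ARD-NMF is non-convex, extraction runs several independent
random initializations (default 10, configurable) and reports a
consensus: the modal K wins; among modal runs the lowest final objective
is chosen.  No per-sample reweighting is applied to hypermutators — the
channel expansion is the mechanism that keeps them from dominating.

Per-mutation process attribution uses the fitted factors:
P(signature i | channel c, sample p) = w_ci·h_ip / Σ_j w_cj·h_jp.
Channels with zero attributed mass in a sample get a uniform vector with
a warning; they can only matter if a mutation actually falls there.

## Signature comparison and FDR

Signatures are compared in 96-channel space by cosine similarity.  A
concurrent-deficiency process may be represented by two components, so a
two-signature match fits non-negative α₁, α₂ maximizing
cos(α₁C1 + α₂C2, S).  Only the ratio α₁:α₂ matters; the public fitter
optimizes the mixing fraction t = α₁/(α₁+α₂) on [0,1] by a coarse grid
plus bounded scalar refinement.  Non-negativity is enforced because
signatures are densities and the match models an additive combination;
the underlying closed form (a 2×2 normal-equation solution with a
boundary check) is used internally, vectorized over the whole reference
table, when millions of fits are needed; a test pins both routes to each
other at 1e−9.

Two chance backgrounds gauge whether a high combination cosine is
meaningful: (i) the distribution of best matches over all pairs of
discovered signatures against the reference set, excluding each
signature's known true-positive references (the exclusion list is a user
input — it depends on which references the discovered signatures
genuinely represent); and (ii) a permutation null in which each
signature's 96 channel values are shuffled — preserving its sparsity —
and all pairs refit against the full reference, repeated (default
10,000×) to estimate P(best cosine ≥ 0.99) by chance.  No external
signature database is redistributed; a loader accepts COSMIC-format TSVs
and a synthetic peaked reference ships for tests and examples.

## Replication timing and strand asymmetry

The genome is split into timing bins (four quartiles in the toy tracks).
For substitution type S and bin b, the observed count of selected
patients is compared with the flat-rate expectation

    n_exp(p,S,b) = Σ_{c∈S} λ_cp / N_c^global · N_c^bin,
    λ_cp = Σ_i w_ci·h_ip,

where N_c counts mutable positions (opportunities) for channel c.  By
construction Σ_b n_exp = Σ_{c∈S} λ_cp exactly, which is asserted in
tests.  Patients are aggregated ratio-of-sums (observed and expected
summed before dividing), matching the patient-bootstrap error model:
SDs come from resampling patients with replacement (default 1000×).
Patient selection for a repair-defect group follows a configurable
dominance rule (default: the group's signature fraction ≥ 0.75).

Strand asymmetry uses the 12 stranded substitution classes: each of the
six types split by whether the A-or-C base of the mutated pair lies on
the leading- or lagging-strand template.  Densities are counts per
stranded opportunity, normalized per substitution type; asymmetry is the
log2 ratio of complementary classes, NaN when either side is empty (no
pseudo-counts).  SDs come from resampling mutations with replacement
(equivalently, multinomial resampling of the 12-cell count vector).
Strand labels are consumed from a BED-like track giving, per interval,
whether the forward strand is the leading-strand template.

## Event ordering from clonality

If the proofreading defect arose first, mutations from its signature
group E accumulated before MMR loss and should be clonal, while the
concurrent-process signatures C accrue afterwards in both compartments;
hence the one-sided hypotheses

    H0: n_E^c/n_C^c ≤ n_E^s/n_C^s   vs.   Ha: clonal ratio greater

(and likewise for M).  Mutations are called clonal when the lower bound
of their 95% CCF interval exceeds 0.75 and subclonal when the upper
bound is below 0.75 — the closest executable reading of "95% confidence
CCF > 0.75" given interval inputs; straddling or missing intervals are
ambiguous and excluded.  Group masses sum per-mutation probabilities
over each compartment.  Eligible samples need concurrent-group mass of
at least 100 mutations and at least 35% of attributed mass (bounds
inclusive).  The p-value draws Poisson counts at the four masses
(default 10⁶ draws) and counts draws where the clonal ratio fails to
exceed the subclonal one, compared by exact integer cross-products.
Ties count toward the null side (conservative); draws with a zero
denominator are discarded and redrawn, since the ratio event is
undefined there and real masses are large.  Both E-first and M-first
p-values enter one Benjamini–Hochberg family across patients;
significance is q < 0.1.

## Cohort statistics

Proofreading genotype is called exo* from at least one missense mutation
within the exonuclease domain (POLE codons 268–471, POLD1 304–517);
out-of-domain, splice-site and loss-of-function mutations are
discounted, and the recurrent POLE hotspots P286R/V411L are labelled.
Codons are taken as provided (protein space).  Association tests use
Fisher's exact test — two-sided by the minimum-likelihood rule by
default; for the hotspot × MSI-H table the two- and one-sided values
agree at the reported precision — and one-tailed Wilcoxon rank-sum tests
with midranks (exact for small tie-free samples, normal approximation
with continuity correction otherwise).

## Synthetic cohorts

The generator emulates the structure of an endometrial-like exome cohort
without using any real data.  Ground-truth signatures are sparse peaked
vectors over the 1544 channels built around fixed trimer motifs with
seeded random flanking bases: E (T[C>A]T, T[C>T]G), M (CpG C>T plus 1-bp
indel mass), C (G[C>A]T and other motifs distinct from E+M), D, and a
broad background B.  Pairwise cosines are below 0.35, which is what
makes "extraction recovers the truth" a meaningful test.  Genotype
mixtures tie signatures to genotypes (e.g. POLE-MSI ≈ 80% C); burden
ranges span 10²–10⁵ by genotype; microsatellite-indel annotation counts
are Poisson with MSI-dependent means.  Mutations are placed at reference
positions carrying the channel's context on either strand, so context
columns, opportunity counts and strand labels are mutually consistent.
CCFs: clonal mutations get point CCF ≈ N(0.95, 0.03) with ±0.08
intervals, subclonal U(0.1, 0.5) with wider intervals, truncated to
[0, 1]; a small ambiguous band arises naturally and exercises the
exclusion path.  The ordering scenarios mirror the two-event model:
under `pole_first` a configurable fraction (default 0.3) of each doubly
deficient sample's burden is emitted from signature E with clonal CCFs
only; `simultaneous` draws everything from the genotype mixture with a
common clonal fraction.  Optional `timing_bias` and `strand_bias` knobs
multiply placement weights per timing bin or per substitution type's
leading-template positions, giving known effect sizes for calibration
tests.  All draws flow from a single integer seed; output is
byte-identical across calls.  Coordinates are 0-based half-open in
memory; MAF-like files are written 1-based.

What the generator does not emulate: real human genome composition and
exome capture (the reference is i.i.d. random sequence on one contig),
germline variation, mutation clustering, copy-number structure behind
CCF estimates, and the Bethesda assay itself (MSI status follows
genotype by construction).  Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated model,
not robustness to the full messiness of tumor sequencing data.

## Problem sizes and numerical notes

Validation suites run at deliberately modest scale: signature-recovery
uses 60 samples with burdens 500–20,000 and 10 NMF restarts (the modal
K and per-truth cosine ≥ 0.95 are the acceptance quantities); timing
profiles use 30 samples on a 20 kb reference; strand-asymmetry cohorts
use a 1 Mb reference — on much shorter references each pentamer context
occurs only tens of times, and the binomial imbalance of its
leading/lagging opportunities injects spurious asymmetry of order
2δ/ln 2 for context imbalance δ, so ~10⁶ bp keeps that artifact well
inside the bootstrap error; ordering calibration uses 200 simultaneous-
scenario samples and power uses 50 pole-first samples at 2×10⁵ draws per
test (p-resolution far below the BH threshold at these effect sizes),
with 10⁶ draws wherever a p-value itself is the quantity of interest.
Downstream covariate and ordering validations drive the analysis from
the generator's truth model (truth profiles as W, realized exposures as
H) so that their calibration is tested independently of NMF fitting
error; the recovery suite closes that loop separately.

Degenerate inputs: all-zero catalogs and zero-length groups raise;
K_max above min(matrix dims) is clamped with a warning; zero-burden
samples yield NaN activity fractions; empty cohorts produce valid empty
files.  Small ε (1e−12) floors protect the multiplicative updates from
division by zero and keep factors strictly positive.

## Known limitations

- The ARD hyperparameters (a, the data-scaled b, pruning at 1e−8) are
  standard choices, configurable but not re-derived; very flat or very
  low-burden catalogs may prune differently.
- Per-type (not per-channel) opportunity normalization of stranded
  densities; with strongly context-skewed signatures on short
  references the distinction matters (see the 1 Mb note above).
- The helper deriving strand orientation from a timing-track gradient
  is not implemented; strand labels must come from a track.
- The clonality rule trusts the supplied CCF intervals; no purity or
  copy-number modelling is attempted.
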