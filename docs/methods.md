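# Methods

## The model

RNA genes fold into secondary structures whose helical *stems* impose
complementary base pairing; unpaired *loop* regions do not. `stemloop`
scores a structure-annotated alignment under a fixed-effect mixture: loop
columns evolve as independent nucleotides under a 4-state model, and stem
column pairs evolve as single dinucleotide characters under a 4-, 7- or
16-state model, with the partition specified a priori by the consensus
structure.

All models are continuous-time reversible Markov processes with rate
matrix `Q = S diag(π)` off the diagonal, where `S` is a symmetric matrix
of exchangeabilities and `π` the equilibrium frequencies; diagonals make
rows sum to zero and detailed balance `π_i q_ij = π_j q_ji` holds by
construction, so the likelihood is independent of root placement.
Matrices are scaled to one expected substitution per unit time per
character in their own space: per *site* for 4-state models, per
*dinucleotide* for 7- and 16-state models. Transition matrices
`P(t) = exp(Qt)` are computed through the symmetric eigendecomposition
`diag(π)^{1/2} Q diag(π)^{-1/2}`, which is exact for reversible matrices
and remains stable for the very large exchangeabilities used in
projections (see below).

### The foundation-model registry

Eighteen foundation models are registered declaratively: each descriptor
names a frequency structure, a partition of the unordered state pairs
into exchangeability classes, and a flag for whether substitutions
changing both positions of a pair at once are allowed. Four classes:

* **DNA** — HKY and GTR, pairing ignored (always with Γ rates when used
  in mixtures).
* **Stable Pairs** — one free frequency per canonical pair (Watson–Crick
  A:U/U:A, C:G/G:C and wobble G:U/U:G) and a pooled mismatch mass: the
  seven 7-state models 7A–7G, and 16C, which spreads the pooled mass
  equally over the ten mismatch dinucleotides (`π_MM/10` each).
* **Stable Sets** — 16D/16E/16F: the frequency of dinucleotide XY is
  `α π_X π_Y / λ` for Watson–Crick pairs, `β π_X π_Y / λ` for wobble, and
  `π_X π_Y / λ` for mismatches, with `λ` normalizing. Because rates are
  exchangeabilities times target frequencies, α and β shape both the
  equilibrium and the substitution flow. 16F has a single
  exchangeability class; 16E distinguishes transitions from
  transversions at the changing position; 16D additionally permits
  double substitutions. Hence 16F ⊂ 16E ⊂ 16D.
* **All Pairs** — 16A/16B/16I/16J/16K: all 16 frequencies free, with
  single-position exchangeabilities pooled (16I), split by
  transition/transversion (16J, plus doubles in 16K), or given one rate
  per nucleotide exchange as in GTR (16A, plus doubles in 16B).

Within the 7-state family (state order AU, GU, GC, UA, UG, CG, MM): 7A is
the general reversible model; 7B its strand-symmetric restriction; 7C
keeps per-edge rates for single-position changes and into-mismatch rates
but pools double substitutions; 7D reduces to three rates
(single/double/mismatch); 7E keeps two rates (single, mismatch) with free
frequencies and no doubles; 7F is strand-symmetric with per-orbit rates;
7G — the simplest RNA model, with the same four free parameters as HKY —
is strand-symmetric with just one free exchangeability ratio, and is a
restriction of both 7E and 7F.

The exact exchangeability structures of the previously published models
are reconstructed here from their class descriptions and the standard
parameterizations of the RNA-model literature (Tillier-style
single/double/mismatch rate classes, Higgs-style stable sets); the
descriptors ship as human-readable YAML (`stemloop/descriptors/`,
regenerable with `stemloop export-descriptors`) so any transcription
choice is inspectable and overridable without touching engine code.
Structural self-tests pin each descriptor's free-parameter count and the
documented nesting relations.

### Rate heterogeneity, ρ, and the gene rate

Discrete-Γ rates-across-sites uses equal-probability categories whose
rates are the bin means of Γ(shape, shape) (default 4 categories); the
category is mixed at the site level for loops and at the pair level for
stems. Loop models always carry Γ; dinucleotide stem models are offered
with and without it.

Partitioned mixtures carry ρ, the rate of stems relative to loops,
implemented by multiplying stem branch lengths by ρ while leaving the
stem model in its per-dinucleotide unit. The per-nucleotide gene rate is
`r = (1 − p_stem) + p_stem · ρ/2` in loop-rate units for dinucleotide
stems (the 2 converts per-dinucleotide to per-nucleotide) and without
the factor 2 for nucleotide stem models.

## Likelihood and fitting

Log-likelihoods use the pruning recursion over compressed site patterns
with per-pattern rescaling. Ambiguous observations (gap, N, or any
degenerate symbol) take a partial-likelihood vector of ones; a pair with
*either* position degenerate is fully ambiguous in every stem scoring —
including the nucleotide view used by 4-state stem models — so that all
candidates condition on exactly the same data (this is what makes their
likelihoods comparable).

Fitting maximizes exchangeabilities, Γ shapes, ρ, Stable Sets α/β and
optionally branch lengths with L-BFGS-B on log-transformed parameters,
from three starting points (defaults plus seeded perturbations);
convergence failures flag the result rather than raising. Frequencies
are never optimized: they come from empirical counts pooled over the
model's frequency structure, with +0.5 added to zero cells only
(switchable) so no observable state has zero equilibrium frequency.
Stable Sets nucleotide frequencies are stem-region counts, with α/β
free; their starting values are moment-matched from the observed
Watson–Crick/wobble/mismatch masses.

## Cross-state-space model selection

AICc = −2lnL + 2k + 2k(k+1)/(n−k−1), with n counted as loop columns plus
pairs (each pair one character) for every candidate. `k` counts
frequency df (empirical counts are still estimated from the data),
exchangeability df, Γ shapes, ρ, and branch lengths only when they are
optimized — identically for every candidate.

Likelihoods across state spaces are made comparable by projection onto
the 16-state space:

* **4 → 16**: copying the 4-state rates onto single-position changes
  (zero for doubles) with outer-product frequencies reproduces the
  per-column product model exactly — `P16(t) = P4(t) ⊗ P4(t)` — so
  4-state and 16-state likelihoods on pairs are directly comparable with
  no adjustment.
* **7 → 16**: canonical↔canonical rates are copied; the rate from
  canonical pair c into a specific mismatch x is
  `q7(c→MM) · f_x / π_MM` where `f_x` is x's share of the pooled
  mismatch mass; mismatch↔mismatch rates are `σ f_x`. In the σ → ∞
  limit the ten mismatches equilibrate instantaneously and the 16-state
  log-likelihood equals the 7-state one plus
  `Σ log(f_x / π_MM)` over unambiguously observed leaf mismatches: with
  equal shares each term is log(1/10) at no parameter cost; with
  empirical shares the terms use the observed mismatch composition at a
  cost of 9 df. Both variants are evaluated for every 7-state candidate
  and the lower AICc kept. σ = ∞ is never represented literally: oracle
  tests use σ = 1e7 and verify the equivalence tightens along
  1e3 → 1e5 → 1e7.

The selection sweep fits all 70 candidates (2 unpartitioned nucleotide
models + 2 loop × 34 stem options), records per-candidate failures
without aborting, and ranks by AICc with deterministic tie-breaking
(smaller k, then name). Per-candidate seeds derive from the global seed
and the candidate name, so reports are byte-reproducible and removing a
candidate leaves the other rows unchanged.

## Simulator

The generator draws root states from the stationary distribution and
propagates them with exact branch transition probabilities (no
event-level simulation), drawing a Γ category per site or pair —
precisely the process the likelihood integrates, which is what makes it
a valid oracle for recovery tests. Layout is a single nested helix
flanking the loop block, so simulated alignments round-trip through the
Stockholm/FASTA readers. 7-state stems are emitted through their
σ-infinite 16-state projection with equal mismatch shares (the MM state
has no unique letters). The seed fully determines the output.

What the generator does *not* emulate: indels (beyond the absence of
gaps), alignment error, paralogy, arm switching, or structure change
over the tree. Passing recovery and selection tests therefore
demonstrates correctness of the inference machinery under the model
class, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Validation studies use deliberately modest sizes chosen to exercise the
estimators well into their consistent regime: parameter recovery uses 16
taxa with 200 pairs (Stable Sets α within ±40%) and 2000 sites (HKY κ);
reduced-scale selection studies use 12–16 taxa, 20 replicates, and a
nine-candidate subset spanning all four model classes (unpartitioned
DNA, partitioned nucleotide stems, Stable Pairs 7G/7E/16C, Stable Sets
16D/16F, All Pairs 16I). Optimizer tolerance is 1e-6 in lnL
(`ftol` 1e-10 on the scaled objective); exchangeabilities are bounded in
[1e-4, 1e4], shapes in [0.02, 100], ρ and α/β in [1e-3, 1e3]. Matrix
invariants (detailed balance, zero row sums, stationarity, unit scaling)
are enforced to 1e-10–1e-12. Ties in AICc resolve toward fewer
parameters; the equal-frequency correction wins ties with the empirical
one.

## Known limitations

* Tree topology search is out of scope: fitting is on a fixed input
  topology (branch lengths optionally optimized).
* The 16→7 collapse of a fitted 16-state model is not provided, and σ is
  never treated as a free parameter.
* Exchangeability structures of the previously published foundation
  models are reconstructions from class descriptions, pinned by
  descriptor self-tests, not transcriptions of the original matrices;
  the engine accepts amended descriptors should a discrepancy surface.
* Empirical frequencies with heavy ambiguity can be poorly determined;
  the pseudocount guards degenerate cases but is no substitute for data.
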