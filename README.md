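# stemloop

Substitution-model selection for structured RNA genes.

RNA genes — tRNA, rRNA, snoRNA, microRNA precursors and other noncoding
RNAs — evolve under complementary base pairing in the helical stems of
their secondary structure, so the usual assumption of independently
evolving alignment columns fails exactly where the signal is strongest.
`stemloop` is for phylogeneticists who want to know, for a given
structure-annotated alignment, whether an RNA-specific model fits better
than a nucleotide model, and which one: it fits stem/loop partitioned
mixtures of 4-state nucleotide models (HKY, GTR) and base-pair models on
7 states (the six canonical pairs A:U, U:A, C:G, G:C, G:U, U:G plus one
pooled mismatch state; models 7A–7G) or 16 states (all dinucleotides;
models 16A–16F, 16I–16K), and ranks all 70 candidates by AICc.

Likelihoods computed on different state spaces condition on different
data and cannot be compared directly. `stemloop` implements state-space
projection onto a common 16-state space:

* a 4-state model applied independently to both positions of a pair *is*
  a 16-state model (`P16(t) = P4(t) ⊗ P4(t)`), so nucleotide and
  dinucleotide likelihoods compare directly;
* a 7-state model projects to 16 states in the limit of instantaneous
  exchange among mismatches, where
  `lnL16 = lnL7 + Σ log(f_x/π_MM)` over observed leaf mismatches — each
  term `log(1/10)` under equal mismatch shares (0 df) or the empirical
  share (9 df); both variants are scored and the lower AICc kept.

Everything runs on a fixed tree topology (branch lengths optionally
re-optimized); frequencies come from empirical counts, all other
parameters — exchangeabilities, Γ shape, the stem/loop rate ratio ρ,
the Stable Sets pairing propensities α and β — by maximum likelihood.
A seeded simulator and tree-set comparison utilities (normalized
Robinson–Foulds distance, posterior-set topology overlap) round out the
toolkit. See `docs/methods.md` for the model details.

## Input formats

* Stockholm with a `#=GC SS_cons` dot-bracket line (Rfam-style;
  pseudoknot bracket families `()`, `<>`, `[]`, `{}`, `Aa`–`Zz` accepted),
* FASTA plus a sidecar dot-bracket file, or
* FASTA plus a pair-list file: one `i j` per line, 0-based column
  indices; unlisted columns are loop columns.

`T` is normalized to `U` on load; gaps and `N` are ambiguous, and a pair
with either position degenerate is fully ambiguous in every stem scoring
so that all candidates condition on the same data.

## Worked example

Simulate a small gene (16 taxa; 30 stem pairs under the Stable Sets
model 16D with pairing propensity α = 8, wobble propensity β = 2.5, stem
rate ρ = 1.5; 40 loop sites under HKY+Γ), then let selection try to
recover the generating class:

```python
import stemloop as sl

tree = sl.random_tree(16, seed=7, mean=0.1)
loop = sl.build_model("HKY", {"pi": [0.3, 0.2, 0.25, 0.25],
                              "kappa": 4.0, "gamma_shape": 0.8})
stem = sl.build_model("16D", {"nuc_pi": [0.3, 0.2, 0.25, 0.25],
                              "alpha": 8.0, "beta": 2.5,
                              "rates": {"ts": 3.0, "double": 0.3}})
aln, truth = sl.simulate_alignment(
    sl.SimulationSpec(sl.MixtureModel(loop, stem, rho=1.5), 40, 30,
                      seed=11, tree=tree))

candidates = [
    sl.CandidateSpec("HKY+G", None, partitioned=False),
    sl.CandidateSpec("HKY+G", "HKY+G"),
    sl.CandidateSpec("HKY+G", "7G"),
    sl.CandidateSpec("HKY+G", "16C"),
    sl.CandidateSpec("HKY+G", "16D"),
    sl.CandidateSpec("HKY+G", "16F"),
]
report = sl.select(aln, tree, candidates, seed=1)
print(report.table[["candidate", "class", "lnL", "correction",
                    "k", "n", "aicc", "delta_aicc"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
```

prints

```
     candidate       class     lnL correction  k  n    aicc  delta_aicc
     HKY+G|16D  StableSets -884.87       none 13 70 1802.24        0.00
     HKY+G|16C StablePairs -896.31       none 15 70 1831.51       29.27
     HKY+G|16F  StableSets -908.21       none 11 70 1842.96       40.73
   HKY+G|HKY+G         DNA -956.38       none 11 70 1939.31      137.08
HKY+G (single)         DNA -965.56       none  5 70 1942.06      139.82
      HKY+G|7G StablePairs -821.94  empirical 19 70 2102.66      300.42
```

The generating model 16D wins outright (ΔAICc = 0). The sample size
`n = 70` counts each base pair as one character (40 loops + 30 pairs).
The 7G row shows the projection at work: its raw lnL (−821.94) is
computed on 7 states and *looks* best, but conditioning it onto the
16-state space — here via empirical mismatch shares, at 9 extra df —
reveals the poor fit; comparing raw likelihoods across state spaces
would have picked the wrong model. Both DNA candidates trail the RNA
models by >130 AICc units: the pairing signal is real and strong.

The same sweep is available from the shell:

```sh
stemloop select --alignment gene.sto --tree gene.nwk \
    --models all --seed 1 --out report.tsv --json report.json
stemloop loglik --alignment gene.sto --tree gene.nwk --loop HKY+G --stem 16D
stemloop simulate --spec sim.yaml --seed 3 --out sim.sto --truth truth.json
stemloop treecmp --set-a run1.nwk --set-b run2.nwk --out stats.json
```

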