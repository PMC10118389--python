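# crisprcoevo

Stochastic and mean-field models of bacteria–phage coevolution with CRISPR
adaptive immunity.

Bacteria in a chemostat carry at most one CRISPR spacer; lytic phages carry a
single protospacer, a binary word of length L = 30 that can mutate at burst.
A spacer matching a phage's protospacer cuts the phage's success probability
from pV to pV(1 − e).  Naive bacteria that survive an attack acquire the
attacker's protospacer as a spacer with probability η; spacers are lost at
rate r.  From these few reactions, host and pathogen sequence diversity
emerges spontaneously and stays in steady turnover: new escape mutants
establish, bacteria track them, old clones die out.

The package is for quantitative ecologists and immunologists who want to
simulate this process exactly, predict its steady state analytically, and
compute the population statistics the theory is phrased in:

* **`simulate`** — exact (Gillespie) and tau-leaping engines for the full
  reaction catalogue, with clone-resolved snapshots and per-clone lifetime
  records (birth, parent, establishment, extinction, maximum size).
* **`meanfield`** — the deterministic layer: phage viability index
  A = (BpV − 1)(1 − f)α/(fg), the no-CRISPR totals ñB, ñV, the cubic for the
  spacer-bearing fraction ν with its dominant-balance reductions, and the
  critical effective immunity em\*.
* **`clonetheory`** — establishment probability Pest = 2s₀/(B(s₀ + δ₀)) with
  an exact branching-process oracle, large-clone extinction times, the
  self-consistent diversity m = Pest·μ̄·Text and its closed form
  m³ = a(1 + ln m), and the speed of evolution v = 1/Text.
* **`analysis`** — average and marginal immunity, time-shifted immunity,
  type turnover, clan clustering (single linkage, L1), PCA trajectories,
  Morisita–Horn similarity, signed-rank shift asymmetry.
* **`toymodels`** — CRISPR array-length law aₙ = 1 − (1 − a₁)ⁿ and
  repertoire-assortment scenarios linking diversity to average immunity.
* **`workbench`** — TSV abundance tables, YAML run configs, a synthetic
  fixture generator, and the thin `crispr-coevo` command-line interface.

## Worked example

`examples/01_stochastic_coevolution.py` simulates a small chemostat
(C0 = 1000, e = 0.95, η = 10⁻³, μ = 10⁻⁵) for 3000 bacterial generations:

```
steady state over generations 600-3000 (seed 2):
  bacteria  nB =      254   (spacer-bearing fraction 0.70)
  phage     nV =    19888
  bacterial clones m = 2.79   phage clones = 8.98
  average immunity = 0.344   (e/m = 0.341)
  phage mutants created: 8845
```

A few bacterial clones coexist with a much larger, more diverse phage
population; the measured average immunity — the abundance-weighted pairwise
immunity 1 − Σ nBi nVj pV(i,j)/(pV Σ nBi nVj) — sits right at the e/m
prediction: immunity per clone is diluted by diversity.
`examples/03_clone_theory.py` prints the matching theory at C0 = 10⁴
(Pest = 3.2 × 10⁻⁴, Text ≈ 1.5 × 10³ generations, self-consistent m = 14.3,
closed-form m = 29.7 from a = 5.97 × 10³).  The other examples cover the
mean-field layer, time-shift/turnover analysis and the toy array models.

From a shell, the same machinery is available as
`crispr-coevo simulate|theory|analyze|toy|fixtures` (see `--help`).

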