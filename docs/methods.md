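# Methods

## Model

Bacteria and lytic phage interact in a well-mixed chemostat.  Tracked
species: nutrients C (inflow concentration C0, flow rate F), naive bacteria
nB0, spacer-bearing bacterial clones nBi (one spacer each), and phage clones
nVj (one protospacer each).  Spacers and protospacers are binary words of
length L; identity of the bit pattern defines the type.  Reactions:

* growth: a bacterium divides at rate gC, consuming one nutrient
  (g = gC0/C0; 1/gC0 = 41.7 min is the doubling-time scale, so reported
  "generations" are t·gC0);
* outflow: every bacterium, phage and nutrient leaves at rate F = f·gC0;
  nutrients flow in at F·C0;
* adsorption: a phage meets a bacterium at rate α per pair and is consumed
  whatever happens.  It kills and releases a burst of B offspring with
  probability pV(i,j): pV against naive hosts and mismatched spacers,
  pV(1 − e) against a matching spacer (cross-reactive kernels below).  Each
  of the B·L offspring bits flips independently with probability μ, so a
  fraction 1 − (1 − μ)^L of offspring found (usually new) protospacer types;
* acquisition: a naive bacterium that survives an attack gains the
  attacker's protospacer as its spacer with probability η;
* loss: a spacer is lost at rate r = R·gC0, returning the cell to naive.

Cross-reactivity kernels: all-or-nothing (default), exponential
pV(1 − e·exp(−d/θ)), and step pV(1 − e) for d ≤ θ, with d the L1 (Hamming)
distance.  θ = 0 reproduces the all-or-nothing kernel, including for the
exponential mode.

Deliberately excluded (null-model scope): multi-spacer arrays, spatial
structure, immigration, latency, autoimmunity, anti-CRISPRs, fitness costs.

### Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| C0 | nutrient inflow concentration | 10³–10⁴ in examples | cell equivalents |
| gC0 | maximal growth rate | 2.4 × 10⁻² | min⁻¹ |
| f | normalized outflow | 0.3 | — |
| α | adsorption rate | 2 × 10⁻² / C0 | min⁻¹ |
| B | burst size | 170 | — |
| pV | naive success probability | 0.02 | — |
| e | spacer effectiveness | 0.95 | — |
| R | spacer loss per generation | 0.04 | — |
| η | acquisition probability | 10⁻³ | — |
| μ | flip probability per base per replication | 10⁻⁵ | — |
| L | protospacer length | 30 | bits |

α scales as 1/C0 (equivalently, the culture volume shrinks with C0) so the
deterministic phase diagram is invariant across population sizes.  e, η and
μ defaults are the mid-range values used throughout the examples and the
reduced-scale validation; all are plain constructor arguments.

## Engines

`gillespie_run` is the exact stochastic simulation algorithm over the
aggregate channels (flows, growth, loss, adsorption), with the adsorption
outcome (kill/burst, survive, survive-and-acquire) resolved per event.

`tau_leap_run` advances by steps τ.  Abundant channels (flows, growth,
loss, per-clone adsorption removals) draw Poisson counts from the
state at the step start; rare channels — successful infections (which kill a
specific bacterium and trigger a mutating burst) and spacer acquisitions —
are realized event by event inside the step, so their victim/source
selection and offspring mutations are handled exactly as in the SSA.
Adsorption removals are split by Poisson thinning into kill and non-kill
parts, keeping the phage-side removals and the bacteria-side kills a
consistent decomposition.  The default step policy bounds the expected
number of events per individual per step by `leap_eps` (0.1); a fixed τ can
be supplied instead.  A step that would drive a count negative is clamped to
zero and counted (`n_clamped`; a fraction ~10⁻⁵ of steps in the validation
runs); with `adaptive=True` the step is halved and redrawn instead.  The
source text is silent on both the step rule and negative handling, so these
choices are validated only by agreement with the exact engine
(steady-state means within sampling error; two-sample KS on steady-state
nV not rejected at α = 0.01).

Both engines run on numba-compiled cores over flat integer arrays.  One
seeded PRNG stream per run; runs are reproducible given the seed, but two
runs must not be interleaved in one process.  Initial condition: C = C0,
nB0 = C0(1 − f), and a clonal phage inoculum of size C0 (m_init founder
clones optional).

Clone records: every clone lifetime gets birth time, parent protospacer
(phage), extinction time, and maximum size.  Establishment *fractions* use
the exact per-clone maximum against the threshold; establishment *times*
are read from a power-of-two ladder (first time the clone reached 2^k),
because the default threshold — the measured steady-state mean clone size —
is only known after the run.  The deterministic nV\*/m threshold is
available as an alternative.  A sequence recreated by mutation after
extinction opens a new record.

Run-length convention: 10000·(log10 C0 − 3) generations rounded to the
nearest thousand with a floor of 10000, steady-state window from one fifth
of the run; recording defaults to 15 evenly spaced snapshots over the
steady-state window plus a dense totals table.

## Mean-field layer

Totals (nBs, nV, nB0, C) follow four ODEs with the population-averaged
success probability pVa = pV(1 − e_eff).  Effective immunity e_eff is an
explicit argument everywhere: theory passes e/m, analysis passes a measured
average immunity.  Phages are viable iff A = (BpV − 1)(1 − f)α/(fg) > 1
(equivalently pV > pV0).  The spacer-bearing fraction ν solves a cubic whose
coefficients are built programmatically by expanding the factored
stationarity condition — not transcribed from a printed expansion — and the
root is selected by continuation from e_eff = 0 (where it coincides with
ν̃ = 1/(1 + r/(η̂αñV)), η̂ = η(1 − pV)) and polished by Newton steps until
the ODE residual is below 10⁻⁸ relative.  Dominant-balance reductions
(drop-a, drop-d, −d/c) are exposed with a lookup of which applies where; in
the high-immunity/intermediate-η corner none is reliable and the full root
is recommended.  At e_eff = 1 and η̂ = 0 the cubic factors exactly, giving
the large-e law ν = 1 − 1/(BpV) − (f + R)/((1 − f − R)Bp) with p = pVα/g;
the implemented large-e approximation adds a first-order η̂ correction by
implicit differentiation (the printed series is typographically ambiguous).
The critical effective immunity em\* (where the low-immunity branch
diverges and the totals return to their no-CRISPR values) is exposed in
full and two-term-series form, along with the acquisition probability
η = (A − 1)(BpV − 1)/(AB(1 − pV)) ≈ 0.0113 at which the third denominator
term changes sign.

## Clone-level theory

A new phage mutant is a burst branching process with birth-event rate
β₀ = αpVnB (B offspring per event) and death rate δ₀ = F + αnB(1 − pV);
Pest = 2s₀/(B(s₀ + δ₀)), s₀ = αnB(BpV − 1) − F, is its first-order survival
probability.  The exact fixed-point oracle (smallest root of
δ₀ + β₀q^B = (δ₀ + β₀)q) is kept alongside: the first-order form is within
5% of it for s₀ ≲ 0.06 δ₀ — the regime realized at the self-consistent
steady states — while its error grows like (2/3)·s₀/(s₀ + δ₀) at large B,
reaching ~11% at s₀ = 0.2 δ₀.

Large-clone extinction time: Text = 2nVi(1 − ln(nVi/nV))/((B − 1)(2β + δ))
minutes, with clone-level rates β = αpV(nB − e·nBi) and
δ = F + αnB(1 − pV) + αpV·e·nBi; ×gC0 for generations (all internal rates
stay per-minute; conversion happens once at the reporting boundary).  Using
the stationarity identity 2β + δ = αpVnB(1 − eν/m)(B + 1), this reduces to
the closed form Text ≈ 2(1 + ln m)(ñV/m)(1 − 1/(BpV))/(f(B − 1)) up to
O(1/B), which the tests verify (relative difference < 2/B at defaults).

Diversity: m = Pest·μ̄·Text with equal-clone sizes nVi = nV/m,
nBi = nBs/m and totals at e_eff = e/m.  The balance can have two crossings;
the reported solution is the stable fixed point of m ↦ Pest·μ̄·Text (the
larger, decreasing-through-zero crossing); absence of any crossing is a
flagged "no solution" return, typical of small total populations.  A
warning is emitted when Text falls below the spacer-acquisition timescale
1/D, D = αη̂(nV/m)nB0/gC0 per generation — a conservative flag for the
clonal-interference regime where the balance overestimates diversity.  The
closed form m³ = a(1 + ln m) uses
a ≈ 4eμLη̂(gC0(1 − f))³/(B²α²pV³r); its exact-ν̃ counterpart and the
perturbative solution around z₀ = (ln a + 3)/3 are also exposed.  The
closed-form establishment probability
Pest ≈ [2(eη̂α)²/(μLBr²)]^{1/3} and speed
v ≈ αBf·[eμηL(1 − pV)/(2α²B²r)]^{1/3} follow by composition from the same
reductions; both compositions are kept as unit tests (the speed formula's
prefactor is αBf — the product — which is the only reading consistent with
composing Text, m and a).

First-acquisition timing: with clone growth n(t) = e^{s₀t} and acquisition
rate a_acq = αη(1 − pV)nB0, the first-acquisition density is
P(t) = a_acq·e^{s₀t}·exp(−(a_acq/s₀)(e^{s₀t} − 1)), mean
⟨t⟩ = e^{a_acq/s₀}Γ(0, a_acq/s₀)/s₀, giving the clone-size floor
e^{s₀⟨t⟩} below which bacteria have typically not yet acquired.

## Analysis layer

Average immunity 1 − Σ nBi nVj pV(i,j)/(pV Σ nBi nVj) accepts either
sequence types (kernel-aware, including cross-reactivity) or opaque labels
(δ-matching); pV cancels in the ratio.  Time-shift curves interpolate both
series linearly onto the minimum sampling interval and average the
statistic over all pairs at each signed delay; the protospacers-per-phage
multiplier for data-derived tables is a user-supplied scalar, never
estimated from the data (values above 1 after multiplication are reported
as-is).  Head/tail trimming is explicit in points (default none).  Turnover
is the fraction of types present at t still present at t + Δ; presence is
count > 0 after interpolation.  Clans are single-linkage clusters under L1
with merges strictly below the cut (default 2): connected components of the
one-mutation graph.  PCA axes are fitted on the per-time-normalized phage
matrix only and both populations are projected.  The signed-rank shift test
drops zero differences; fully tied input is reported as degenerate with
p = 1 rather than an error.

## Synthetic fixtures

`generate_fixture` emulates the statistical shape of experiment-derived
count tables: exponential clone sizes (rounded, floor 1), a tunable shared
fraction of type labels between the two populations, per-step type death
and replacement, and multiplicative log-normal size jitter.  It does not
emulate sequencing noise, detection thresholds, fuzzy type grouping, or any
mechanistic coupling between the populations, so analyses on fixtures
validate plumbing and statistics, not biology; mechanistic claims are
tested on simulator output.

## Reduced-scale validation conditions

The stochastic checks run at deliberately small problem sizes chosen once:

* engine agreement: C0 = 10³, e = 0.3, η = 10⁻³, μ = 10⁻⁵, 600 generations,
  5 seeds per engine, steady window from generation 120;
* sub-threshold extinction: pV = 0.005 < pV0, C0 = 10³, 20 replicates,
  500 generations;
* parameter recovery: C0 = 10³, e = 0.95, η = 10⁻³, μ = 10⁻⁵,
  3000 generations, snapshots every 20 generations from generation 600,
  first five seeds whose phage population survives the run (stochastic
  phage extinction is frequent at this C0 and e — as expected for small
  populations with strong immunity — and the steady-state theory applies to
  coexisting runs).  Establishment is compared against Pest evaluated at
  each run's measured mean nB, mirroring how measured totals feed the
  theory expressions.

At these scales the self-consistent m is ~3 and fluctuations are large;
agreement criteria are correspondingly coarse (factor-2 on m and on
immunity vs e/m, 3 standard errors on establishment).  Larger C0 tightens
all of them at proportionally higher cost.

## Numerical choices and degenerate inputs

Cubic roots via the companion matrix (`numpy.roots`) with continuation and
Newton polish; quadratic reductions may return NaN outside their regime and
do so silently (they are approximations, labelled as such).  μ = 0 short-
circuits all mutation machinery; η = 0 gives ν = 0; A ≤ 1 raises for
quantities that presuppose coexistence and returns a flagged bacteria-only
fixed point from `steady_state`.  Establishment times are quantized upward
to the power-of-two ladder rung at or above the threshold.  Sequences are
stored as unsigned integers (bit i = site i); serialization is always the
site-0-first 0/1 string, so on-disk tables are unambiguous.

## Known limitations

The tau-leaping acquisition sources are sampled from step-start phage
abundances; within-step correlations between acquisition and burst are
ignored (negligible at the default step bound).  The clonal-interference
warning threshold is conservative: it flags only regimes where large-clone
turnover outpaces acquisition outright, while mild interference (low η,
high μ) already biases the diversity balance upward.  The analysis layer
treats type identity as exact; fuzzy similarity grouping of real sequencing
reads is out of scope.
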