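"""Clone-level predictions: establishment, extinction, emergent diversity.

The steady-state number of coexisting clones m balances how often new phage
mutants appear (mu_bar), how many escape early stochastic extinction
(Pest), and how long established clones persist (Text): m = Pest mu_bar
Text.  The closed form m^3 = a (1 + ln m) makes the surprising 1/3-power
dependence on (e eta mu) explicit, and the speed of evolution is the
reciprocal of the extinction time.
"""

import crisprcoevo as cc

p = cc.Params(C0=1e4, e=0.95, eta=1e-3, mu=1e-5)
tb = cc.theory_bundle(p)

print(f"initial mutant rates:  s0 = {tb.s0:.3e}/min, delta0 = {tb.delta0:.3e}/min")
print(f"establishment probability Pest = {tb.Pest:.3e}")
print(f"effective mutation rate mu_bar = {tb.mu_bar:.2f} per generation")
print(f"large-clone extinction time Text = {tb.Text:.0f} generations")
print(f"self-consistent diversity m = {tb.m_pred:.1f}")
print(f"combined parameter a = {tb.diversity_a:.3g} -> closed-form m = "
      f"{tb.m_closed_form:.1f}")
print(f"speed of evolution v = 1/Text = {tb.v_pred:.2e} mutations/generation"
      f"  (closed form {tb.v_closed_form:.2e})")

# timing of the first spacer acquisition from a growing escape clone
st = cc.steady_state(p, p.e / tb.m_pred)
tot = st.counts(p.C0)
acq = cc.acquisition_time(p, s0=tb.s0, nB0=tot["nB0"])
print(f"\nfirst spacer acquisition: mean t = {acq['t_mean_generations']:.0f} "
      f"generations, clone size floor ~ {acq['size_at_mean']:.0f}")
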