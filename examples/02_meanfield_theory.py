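"""Deterministic theory of the total populations.

Where do phages stop being viable, what do the coexistence totals look like
without immunity, and how do they shift as the population's average
immunity ("effective e") rises?  The critical effective immunity em* marks
where the low-immunity branch of the spacer-bearing fraction diverges and
the system behaves as if CRISPR were absent.
"""

import crisprcoevo as cc

p = cc.Params(C0=1e4)

A, pV0 = cc.phage_threshold(p)
print(f"phage viability index A = {A:.3f}  (A > 1: coexistence)")
print(f"extinction threshold pV0 = {pV0:.4g}  (default pV = {p.pV})")

nB, nV = cc.no_crispr_steady_state(p)
print(f"no-CRISPR totals: nB~ = {nB:.3g} ({nB/p.C0:.2f} C0), "
      f"nV~ = {nV:.3g} ({nV/p.C0:.1f} C0)")

print("\n e_eff    nB/C0    nV/C0     nu    regime")
for e_eff in (0.0, 0.05, 0.1, 0.2, 0.5, 0.95):
    st = cc.steady_state(p, e_eff)
    print(f"  {e_eff:4.2f}   {st.x_star:6.3f}   {st.y_star:6.2f}  {st.nu_star:5.3f}"
          f"   {st.regime}")

crit = cc.critical_effective_e(p)
print(f"\ncritical effective immunity em* = {crit['em_star_full']:.3f} "
      f"(series {crit['em_star_series']:.3f})")
print(f"eta sign-change threshold = {crit['eta_sign_threshold']:.4g}")
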