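"""Global multi-cycle SPR fit and effective-rate summary.

Generates a synthetic multi-cycle sensorgram for a host whose effector
accelerates target dissociation 2,400-fold (base off-rate 1e-5 s^-1),
with 95 % of captured host responsive to effector and 0.5 % noise, then
recovers the rates by globally fitting the chip model across all cycles
and summarizes the effective rate k_eff([E]) with a constrained hyperbola.
"""

import numpy as np

from fdkin import ChipParams, NoiseModel, gen_cycleset, global_fit, summarize_fd
from fdkin.synth import spr_design_for

truth = ChipParams(
    k_off_T_H=1e-5,      # base target off-rate, s^-1
    k_off_T_HE=2.4e-2,   # accelerated off-rate from the ternary complex
    k_on_TH_E=1e6,       # effector on-rate to the loaded host, M^-1 s^-1
    k_off_TH_E=1e-3,     # effector off-rate from the ternary complex
    k_off_T_Hn=2e-5,     # off-rate of the unresponsive complex
    f_responsive=0.95, a_TH=1.0, a_THE=1.15, a_THn=1.0,
)
design = spr_design_for(truth)  # zero-[E] cycle + twofold dilution to 2 uM
cycles = gen_cycleset(truth, design, NoiseModel(sigma_frac=0.005, seed=1))
print(f"generated {len(cycles)} cycles at [E] =",
      ", ".join(f"{c * 1e9:.0f} nM" for c in cycles.concentrations))

fit = global_fit(cycles)
p = fit.params
print("\nglobal fit of the chip model:")
print(f"  k_off_T:H   = {p.k_off_T_H:.3e} s^-1   (true 1.000e-05)")
print(f"  k_off_T:HE  = {p.k_off_T_HE:.3e} s^-1   (true 2.400e-02)")
print(f"  f_responsive = {p.f_responsive:.3f}          (true 0.950)")
for w in fit.warnings:
    print(f"  note: {w.split(':')[0]}")

E_grid = np.geomspace(4e-9, 8e-6, 12)
series, fold = summarize_fd(p, E_grid)
print(f"\nk_eff rises from {series.k_app[0]:.2e} to {series.k_app[-1]:.2e} s^-1 "
      f"across the effector grid")
print(f"fold acceleration k_off_T:HE / k_off_T:H = {fold:,.0f}")
print(f"half-maximal effector concentration K_1/2 = {series.params['K_half'] * 1e9:.1f} nM")
print(
    "\nThe fold change is the headline figure of merit of a designed"
    "\nfacilitated-dissociation system; K_1/2 marks where the effector"
    "\nachieves half of the maximal rate increase."
)
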