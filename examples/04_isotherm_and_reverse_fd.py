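"""Equilibrium affinity and reverse facilitated dissociation.

First fits the exact quadratic binding isotherm to a synthetic polarization
titration (including a tight-binding case where only an upper bound can be
reported), then characterizes facilitated dissociation in the reverse
direction: labelled effector leaving the host faster as target accumulates.
"""

from fdkin import NoiseModel, fit_isotherm, fit_reverse_fd, gen_competition_courses, gen_fp_titration
from fdkin.synth import NOISELESS, ExperimentDesign

# --- measurable affinity -------------------------------------------------
design = ExperimentDesign(top_conc=1e-6, n_points=24, include_zero=True)
df = gen_fp_titration(K_d=1e-8, probe_conc=5e-10, P0=40.0, P1=160.0,
                      design=design, noise=NoiseModel(sigma_frac=0.002, seed=4))
iso = fit_isotherm(df["conc_M"], df["polarization_mP"], probe_conc=5e-10)
print(f"titration fit: K_d = {iso.K_d * 1e9:.2f} nM (true 10.00 nM), "
      f"P0 = {iso.P0:.1f} mP, amplitude = {iso.P1:.1f} mP")

# --- affinity too strong for the probe ----------------------------------
df2 = gen_fp_titration(K_d=1e-11, probe_conc=1e-9, P0=40.0, P1=160.0,
                       design=design, noise=NOISELESS)
iso2 = fit_isotherm(df2["conc_M"], df2["polarization_mP"], probe_conc=1e-9)
print(f"tight-binding titration: reported '{iso2.reported_affinity}' "
      "(fit lies below the probe concentration)")

# --- reverse facilitated dissociation ------------------------------------
rev_design = ExperimentDesign(top_conc=16e-6, dilution_fold=2.0, n_points=10,
                              include_zero=True, duration_s=2000.0,
                              slow_duration_s=3.5e5, sampling_interval_s=4.0)
courses = gen_competition_courses(
    "reverse",
    {"k_off_TH_E": 1e-2, "K_half": 1e-6, "k_off_H_E": 1e-5, "S0": 40.0, "S1": 120.0},
    rev_design, NoiseModel(sigma_frac=0.002, seed=9),
)
series = fit_reverse_fd([(tc.metadata["conc_M"], tc) for tc in courses])
p = series.params
print("\nreverse facilitated dissociation (effector release vs [target]):")
print(f"  base effector off-rate k_off_H:E   = {p['k_off_H_E']:.2e} s^-1 (true 1.0e-05)")
print(f"  accelerated off-rate   k_off_TH:E  = {p['k_off_TH_E']:.2e} s^-1 (true 1.0e-02)")
print(f"  half-maximal target    K_1/2       = {p['K_half'] * 1e6:.2f} uM (true 1.00 uM)")
print(
    "\nStrain in the ternary complex acts on both partners: the target also"
    "\naccelerates effector release, here by ~1000-fold at saturation."
)
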