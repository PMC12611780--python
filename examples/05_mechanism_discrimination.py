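"""Discriminate induced-fit from conformational-selection effector binding.

Simulates effector-association experiments (host pre-loaded with target,
effector concentration series by twofold dilution) for both mechanisms,
fits the apparent on-rate at each concentration, and lets model selection
decide between a linear and a saturating concentration dependence.
"""

from fdkin import NoiseModel, RateConstantSet, fit_single_exponential, gen_association_courses, select_rate_law
from fdkin.synth import ExperimentDesign

rates = RateConstantSet(
    k_on_TH=1e6, k_off_TH=9e-5, k_on_HE=1e7, k_off_HE=5e-6,
    k_on_THE_viaE=1e5, k_off_THE_toE=1e-5,
    k_switch=5e-3, k_unswitch=5e-2, k_off_THE_toT=1e-2,
)
design = ExperimentDesign(top_conc=2e-6, n_points=12, include_zero=False)

for topology in ("induced_fit", "conformational_selection"):
    courses = gen_association_courses(topology, rates, design,
                                      NoiseModel(sigma_frac=0.005, seed=2))
    concs = [tc.metadata["conc_M"] for tc in courses]
    kapps = [fit_single_exponential(tc, "rise").reported_rate for tc in courses]
    law, fits = select_rate_law(concs, kapps)
    print(f"{topology}: k_app spans {min(kapps):.2e} .. {max(kapps):.2e} s^-1 "
          f"-> selected law: {law}")
    if law == "hyperbolic":
        sat = fits[law].params["k_max"] + fits[law].params["k_base"]
        print(f"  saturating rate = {sat:.2e} s^-1 "
              f"(the switch rate k_switch = {rates.k_switch:.2e} s^-1)")
    else:
        print(f"  slope = {fits[law].params['k_on']:.2e} M^-1 s^-1 "
              f"(the effector on-rate {rates.k_on_THE_viaE:.2e} M^-1 s^-1)")

print(
    "\nA flexible effector binds the closed state directly, so its apparent"
    "\non-rate grows linearly with concentration; a rigid effector must wait"
    "\nfor the switch to open and its series saturates at k_switch."
)
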