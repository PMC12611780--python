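"""Simulate target release under the three competition mechanisms.

Builds the mass-action network for mutually exclusive competition,
conformational selection and induced fit with one shared rate set, then
integrates target release from a pre-formed target-host complex under
excess effector and prints the half-time of bound target for each pathway.
"""

import numpy as np

from fdkin import RateConstantSet, build_network, simulate

rates = RateConstantSet(
    k_on_TH=1e6, k_off_TH=9e-5,          # target-host binding
    k_on_HE=1e7, k_off_HE=5e-6,          # effector-host binding
    k_on_THE_viaE=1e6, k_off_THE_toE=1e-3,   # effector on/off the loaded host
    k_off_THE_toT=1e-2,                  # accelerated target release from THE
    k_switch=1e-3, k_unswitch=1e-2,      # closed <-> open switch rates
)

t = np.linspace(0, 40000, 2000)
h0, e0 = 1e-8, 1e-5  # 10 nM complex, 10 uM effector (saturating)

print(f"target release from a pre-formed complex under {e0 * 1e6:.0f} uM effector\n")
for topology in ("mutually_exclusive", "conformational_selection", "induced_fit"):
    net = build_network(topology, rates)
    traj = simulate(net, {"TH_X": h0, "E": e0}, t)
    bound = traj["TH_X"] + traj.get("THE", 0.0) + traj.get("TH_Y", 0.0)
    idx = np.argmax(bound < 0.5 * h0)
    half = t[idx] if idx > 0 else float("inf")
    print(f"  {topology:28s} bound-target half-time = {half:8.0f} s")

print(
    "\nMutually exclusive competition releases the target only at its"
    "\nspontaneous off-rate (half-time ln2/k_off_TH ~ 7700 s); the ternary"
    "\npathways accelerate release, and induced fit is fastest because the"
    "\neffector does not wait for the slow opening of the switch."
)
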