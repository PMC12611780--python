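"""Fit single and double exponential decays to dissociation traces.

Generates a noisy single-exponential dissociation trace at the slow
target off-rate 9e-5 s^-1 and a biphasic trace mixing two host
populations, then fits both and prints the recovered rate constants.
"""

import numpy as np

from fdkin import NoiseModel, TimeCourse, fit_double_exponential, fit_single_exponential, gen_decay_trace

# --- single exponential, 0.5 % noise ------------------------------------
tc = gen_decay_trace(9e-5, NoiseModel(sigma_frac=0.005, seed=11),
                     n_half_lives=5.0, sampling_interval_s=1.0)
res = fit_single_exponential(tc)
print(f"single-exponential trace: true k = 9.0e-05 s^-1, "
      f"fitted k = {res.reported_rate:.3e} s^-1 "
      f"(half-time {res.half_time / 3600:.2f} h)")

# --- biphasic trace: two host populations -------------------------------
t = np.arange(0.0, 3000.0, 2.0)
y = 0.05 + 0.7 * np.exp(-1e-2 * t) + 0.3 * np.exp(-1e-4 * t)
res2 = fit_double_exponential(TimeCourse(t, y))
print(f"double-exponential trace: rates {res2.rates[0]:.3e} / {res2.rates[1]:.3e} s^-1, "
      f"amplitudes {res2.amplitudes[0]:.2f} / {res2.amplitudes[1]:.2f}")
print(f"reported rate = {res2.reported_rate:.3e} s^-1 ({res2.selection_rule})")
print(
    "\nThe reported rate follows the faster component whenever it carries at"
    "\nleast 30 % of the total amplitude, mirroring how biphasic sensorgrams"
    "\nfrom mixed host populations are summarized."
)
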