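# Methods

## Reaction networks and simulation

The target/host/effector system is modelled as an elementary mass-action
network in units of molar and seconds. Three topologies are supported.
Mutually exclusive competition contains only the binary complexes TH and
HE. Conformational selection inserts the switch isomerization
TH_X ⇌ TH_Y (rates k_switch, k_unswitch) and allows effector binding only
to TH_Y. Induced fit collapses the transient engagement of a flexible
effector with the closed state into a single committed step
TH_X + E → THE carrying k_on,TH:E; the microscopic rates of the weak
initial encounter are not separately observable in any of the assays
modelled here, so this one-step convention is the minimal model consistent
with the data it must explain (a linear apparent on-rate in [E]). Both
ternary topologies include accelerated target release THE → T + HE and,
when a rate is supplied, the reverse target re-entry T + HE → THE.

Networks are integrated with `scipy.integrate.solve_ivp` (LSODA, rtol
1e-8, atol 1e-12 relative to the largest initial concentration — the
rates span roughly 1e-6 to 1e5 and the systems are stiff). Negative
concentrations beyond tolerance and conserved-total drift above 1e-6
relative are treated as integration failures, not silently clipped:
hiding either would mask model or parameter errors. Conservation of total
target, host and effector is audited from a species composition table on
every call.

A `RateConstantSet` may be constructed with an exactly closed
thermodynamic cycle (T + H + E ⇌ TH ⇌ THE ⇌ HE): one ternary rate is
solved from the other seven so the product of equilibrium constants
around the cycle is 1. A direct consequence is the mutuality of
allosteric destabilization — the factor by which saturating effector
weakens target binding equals the factor by which saturating target
weakens effector binding — which the test suite asserts.

## Closed-form rate laws

Four laws cover the dose–response analyses:

- linear: k_app = k_on[E] + k_off (one-step binding; flexible effector);
- conformational-selection slow relaxation:
  ½(k_s+k_u+k_on[E]+k_off) − ½√((k_s+k_u−k_on[E]−k_off)² + 4 k_u k_on[E]),
  the smallest-magnitude nonzero eigenvalue of the linear 3-state system,
  saturating at k_switch. Note that it is monotone increasing in [E] only
  when k_off ≤ k_switch (the tight-effector regime in which the law is
  used; with k_off above k_switch the slow relaxation instead decreases
  towards the plateau);
- hyperbolic: k_max·c/(K_1/2 + c) + k_base, for effective rates of the
  full process in either direction;
- the exact quadratic binding isotherm f_bound([H]; [E]_tot, K_d), valid
  when probe and titrant concentrations are comparable. At [E]_tot = 0 the
  analytic dilute limit [H]/([H]+K_d) is returned rather than NaN.

## Trace fitting

Exponential fits use variable projection: baselines and amplitudes enter
the model linearly and are solved exactly by linear least squares at every
trial rate, while the rate(s) are optimized in log space (positivity
without constraints). Multi-start seeds at {1e-5 … 1e-1} s⁻¹ plus a
data-driven seed (3 / span) guard against local optima; starts that
disagree on the best objective by more than 1e-6 relative attach a
multimodality warning. Covariances come from the Jacobian at the optimum.
Fits whose amplitude is indistinguishable from the residual noise (below
twice the residual RMS) fail loudly.

Double-exponential fits report the faster component when it carries at
least 30 % of the total amplitude, otherwise the larger-amplitude
component; the rule applied is recorded verbatim in each result. When the
two components are indistinguishable (rate ratio < 3 or amplitude ratio
> 20) the fit degrades to a single exponential with a warning.

Dose–response fits default to inverse-rate weighting of residuals: rate
constants within one series span decades, and their errors scale roughly
with the rate, so relative residuals are the variance-stabilized choice
(unweighted fitting is available via `weighting="absolute"`). The
conformational-selection fit applies a box bound k_off ≤ 1e-4 s⁻¹, the
regime in which that law is employed. Mechanism discrimination between the
linear and hyperbolic laws uses an extra-sum-of-squares F test at
α = 0.01 (the linear law is the large-K_1/2 limit of the hyperbola, so
the nested test is exact in form); non-nested comparisons fall back to
small-sample AIC.

Equilibrium titrations are fitted with the quadratic isotherm; when the
fitted K_d falls below the probe concentration, the affinity is reported
only as the upper bound "K_d < [probe]" (tight-binding flag), since the
titration shape no longer constrains the value.

## The multi-cycle chip model and global fit

Within a dissociation phase the effector concentration is constant under
flow, making the three-species chip ODE linear. Trajectories are therefore
propagated exactly through the eigen-decomposition of the 2×2
[THE, TH] block (THn is decoupled), which is both faster and more accurate
inside an optimization loop than adaptive integration; the test suite
cross-checks this propagator against `solve_ivp` to 1e-8.

Between cycles the chip is re-loaded: free sites are filled with fresh
host, a fraction f_responsive responsively and the remainder joining the
unresponsive pool, with any ternary complex remaining at the end of a
cycle counted as free sites (the model assumes the effector-bound state
clears between cycles). When the fitted k_off,TH:E times the inter-cycle
gap is below 3, a warning flags that this clearance assumption is dubious.

The global fit varies five rate constants (log10 space, off-rates bounded
in [1e-7, 1] s⁻¹, k_on,TH:E in [1e2, 1e7] M⁻¹s⁻¹), f_responsive in
[0.5, 1], three response amplitudes in [0.01, 10], and per-cycle amplitude
factors f_n in [0.5, 2] for n ≥ 2 — f_1 is fixed to 1 because the f_n
carry a pure gauge freedom against the amplitudes, and anchoring the first
cycle is the simplest way to break it. Only dissociation curves enter the
objective, equally weighted (association phases serve solely to set the
loading recursion). Initialization is data-driven: per-cycle
single-exponential fits seed the fast and slow rates and a crude
hyperbolic fit seeds k_on,TH:E. Every result carries a standing warning
that (k_on,TH:E, k_off,TH:E) covary tightly and are not individually
determined by dissociation data; with effector binding fast, the
dissociation kinetics are governed by the two target-release rates, which
is also why scaling that pair jointly leaves the fitted off-rates
unchanged (asserted in the tests).

A single cycle, in contrast, cannot even order the two off-rates: the sum
and the shifted product of (k_off,T:H, k_off,T:HE) are the only
combinations a one-concentration bi-exponential constrains, leaving an
exact two-branch ambiguity. Fitting globally across a concentration series
is what removes it.

The effective rate k_eff([E]) is defined through the half-time of total
bound target in the simplified two-species system started from [TH] = 1:
the bi-exponential closed form is root-solved with Brent's method
(relative tolerance 1e-12, horizon extended geometrically up to 1e12 s).
k_eff is exactly hyperbolic in [E] only in the rapid-equilibrium limit
(k_on[E] and k_off,TH:E large against k_off,T:HE, with
K_1/2 = k_off,TH:E/k_on); outside that limit the constrained hyperbolic
summary (plateau and baseline pinned to the fitted off-rates, K_1/2 free)
is a deliberate approximation, and the fold acceleration — a pure ratio of
fitted rates — does not depend on it.

## Synthetic assays: what they emulate and what they do not

The generators produce every assay class with embedded ground truth:
multi-cycle sensorgrams (loading recursion, unresponsive-host
accumulation, per-cycle amplitude factors), FP titrations on the exact
isotherm, forward/reverse competition courses, FRET transfer with a
logistic baseline drift, luminescence activation/decay, and
effector-association series simulated from the full mass-action network
for either mechanism (with the target-release channels clamped, as the
excess-target protocol achieves experimentally).

Default study conditions: effector series by twofold dilution from 2 μM
with one zero-effector cycle first (2 h at 1 Hz): for fold changes in the
thousands the lowest dilution still dissociates far faster than the base
rate, so without a zero-effector phase the base off-rate would rest on
extrapolating the hyperbola over several decades. Effector cycles last
five accelerated half-lives,
bounded to [10 min, 2 h] at 1 Hz; noise is additive Gaussian with σ =
0.5 % of the full-scale amplitude. Truth values used throughout the
round-trips: k_on,TH:E = 1e6 M⁻¹s⁻¹, k_off,TH:E = 1e-3 s⁻¹ (fast effector
binding), f_responsive = 0.95, amplitudes a_TH = 1.0, a_THE = 1.15 (the
bound effector adds mass), a_THn = 1.0, k_off,T:Hn = 2e-5 s⁻¹, f_n = 1.
Seeds are mandatory and a fixed seed reproduces a dataset byte-for-byte
(three canonical fixtures carry frozen SHA-256 digests).

Real SPR data differ in ways the generator deliberately omits:
heteroscedastic and correlated noise, bulk refractive-index jumps, mass
transport limitation, baseline drift other than the logistic form, and
surface heterogeneity beyond a single unresponsive population. Passing
round-trips therefore demonstrate estimator correctness and
identifiability under the stated noise model, not robustness to every
instrument artefact.

## Numerical and design choices

- Degenerate eigenvalues of the 2×2 chip block (a measure-zero parameter
  set) are handled by a 1e-8 relative nudge of one diagonal entry.
- The unresponsive pool [THn] accumulates monotonically across cycles
  provided the unresponsive complex is stable on the cycle timescale
  (k_off,T:Hn × duration small); with a fast-dissociating unresponsive
  pool the recursion can legitimately deplete it, so the monotonicity
  property is asserted only in the stable regime the model is meant for.
- Coverage checking compares phase durations against three half-lives at
  the fastest fitted rate; short phases attach warnings rather than
  failing, mirroring how an experimentalist would flag but still analyse a
  truncated run.
- Per-cycle residuals are equally weighted; no noise-variance weighting is
  applied (the generator's additive noise is homoscedastic within a run).
- The recovery harness draws parameters log-uniformly from ranges chosen
  so every drawn system is measurable within the emulated phase durations:
  k_off,T:H in [2e-5, 2e-4] s⁻¹, fold in [20, 2000], k_on,TH:E in
  [3e5, 3e6] M⁻¹s⁻¹, k_off,TH:E in [3e-4, 3e-3] s⁻¹, f_responsive uniform
  in [0.85, 0.98].
- Round-trip problem sizes in the test suite use 0.1 Hz sampling of the
  same designs (about 11,000 points per cycle set) so the full suite runs
  in well under five minutes; the acceptance script uses the full 1 Hz
  designs.

## Known limitations

- No stochastic (Gillespie) engine: all assay copy numbers are
  macroscopic, so deterministic ODEs suffice.
- No mass-transport or bivalent-analyte SPR corrections, and no modelling
  of capture-surface chemistry.
- The induced-fit one-step convention cannot resolve the microscopic
  encounter-complex rates, only their product as an effective on-rate.
- Confidence intervals are Jacobian-based (local, Gaussian); bootstrap
  resampling is not built in.
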