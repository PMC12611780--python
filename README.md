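# fdkin

Kinetic modelling and inference for engineered **facilitated-dissociation**
systems: protein "hosts" built from a conformational switch fused to a
binder, designed so that an effector ligand allosterically ejects a tightly
bound target through a strained ternary intermediate.

The package is for protein engineers and biophysicists who characterize
such switches with surface plasmon resonance (SPR), fluorescence
polarization (FP), FRET and luminescence assays, and who need to turn raw
multi-cycle sensorgrams and titrations into rate constants, mechanism
assignments and fold-acceleration numbers.

## The model

A target T, host H (closed state X, open state Y) and effector E compete
through three possible pathways:

- **mutually exclusive competition** — E binds only free host; target
  release is limited by the spontaneous off-rate k_off,T:H;
- **conformational selection** — E binds only the open state TH_Y, so
  ternary-complex formation saturates at the switching rate k_switch;
- **induced fit** — a flexible E engages the closed state TH_X directly and
  drives the conformational change, bypassing the slow switch.

Both ternary pathways release the target from the strained complex THE at
the accelerated rate k_off,T:HE; the **fold acceleration**
k_off,T:HE / k_off,T:H is the headline figure of merit, and
K_1/2 is the effector concentration giving half the maximal rate increase.

On an SPR chip, dissociation in cycle *n* under effector flow follows

    d[THE]/dt = −k_off,T:HE [THE] + k_on,TH:E [TH][E] − k_off,TH:E [THE]
    d[TH]/dt  = −k_off,T:H [TH]  − k_on,TH:E [TH][E] + k_off,TH:E [THE]
    d[THn]/dt = −k_off,T:Hn [THn]

where THn is an effector-unresponsive host population that accumulates
across cycles (a fraction 1 − f_responsive of each re-loading), with the
response read out as S = f_n (a_TH [TH] + a_THE [THE] + a_THn [THn]).
`fdkin` fits this model **globally across all cycles**, then converts the
fitted rates into an effective first-order rate k_eff([E]) = ln 2 / t_1/2
of total bound target and summarizes it with the constrained hyperbola
k_eff = k_off,T:HE·[E]/(K_1/2 + [E]) + k_off,T:H.

Closed-form laws (linear and conformational-selection apparent on-rates,
the exact quadratic binding isotherm, single/double exponentials with a
principled reported-rate rule, sigmoid baseline drift) cover the companion
FP/FRET/luminescence assays. Because no raw kinetic data accompany the
published designs, a synthetic-assay module generates every data type with
known ground truth, so each stage is validated by parameter recovery.

## Worked example

`examples/03_global_spr_fit.py` generates a synthetic multi-cycle
sensorgram for a host with a 2,400-fold designed acceleration (base
off-rate 1e-5 s⁻¹, 95 % responsive host, 0.5 % noise) and re-derives the
kinetics by the global fit:

```
generated 8 cycles at [E] = 0 nM, 31 nM, 62 nM, 125 nM, 250 nM, 500 nM, 1000 nM, 2000 nM

global fit of the chip model:
  k_off_T:H   = 9.815e-06 s^-1   (true 1.000e-05)
  k_off_T:HE  = 2.402e-02 s^-1   (true 2.400e-02)
  f_responsive = 0.950          (true 0.950)
  note: weak_identifiability
  note: slow_ternary_clearance

k_eff rises from 3.09e-03 to 2.39e-02 s^-1 across the effector grid
fold acceleration k_off_T:HE / k_off_T:H = 2,447
half-maximal effector concentration K_1/2 = 30.9 nM
```

The two fitted off-rates land within 2 % of the generator truth; the fold
change (2,447 vs 2,400) is recovered within the 5 % tolerance the round-trip
suite enforces. The `weak_identifiability` note flags that the effector
binding pair (k_on,TH:E, k_off,TH:E) covaries tightly and is not separately
determined by dissociation data — only the target-release rates are.

The other examples cover mechanism simulation (`01`), exponential trace
fitting (`02`), isotherms and reverse facilitated dissociation (`04`) and
mechanism discrimination by model selection (`05`). A thin CLI wraps the
same pipeline: `fdkin simulate|fit-trace|fit-global|characterize-forward|
characterize-reverse|recover`.

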