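"""Synthetic assay generators with embedded ground truth.

Every assay class fitted by this package can be emulated with known
parameters and controlled additive Gaussian noise, so each fitting stage is
testable by parameter recovery: multi-cycle SPR sensorgrams with host
re-loading and accumulation of an effector-unresponsive population,
fluorescence-polarization titrations obeying the exact quadratic isotherm,
and exponential competition/transfer/luminescence time courses with an
optional sigmoid baseline drift.

Default noise is additive Gaussian with sigma 0.5 % of the full-scale
amplitude.  Seeds are mandatory: a fixed seed reproduces a dataset
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import sigmoid_drift
from .laws import fraction_bound, kapp_hyperbolic, kapp_linear
from .spr import ChipParams, Cycle, CycleSet, chip_trajectory, propagate_cycles, response_model
from .timecourse import TimeCourse

#: default fractional noise (of full-scale amplitude)
DEFAULT_NOISE_FRAC = 0.005


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise; ``sigma_frac`` scales with full-scale amplitude."""

    sigma: float = 0.0
    sigma_frac: float = DEFAULT_NOISE_FRAC
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.sigma_frac < 0:
            raise ValueError("noise sigmas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, y: np.ndarray, full_scale: float, rng: np.random.Generator) -> np.ndarray:
        s = self.sigma + self.sigma_frac * full_scale
        if s == 0:
            return y.copy()
        return y + rng.normal(0.0, s, size=y.shape)


NOISELESS = NoiseModel(sigma=0.0, sigma_frac=0.0, seed=0)


@dataclass
class ExperimentDesign:
    """Dilution series, phase durations and sampling of an emulated experiment.

    Defaults mirror common practice for these assays: twofold serial
    dilution, 1 Hz sampling, a long (2 h) dissociation phase for slow
    kinetics and shorter phases for effector-accelerated kinetics.
    """

    top_conc: float = 2e-6
    dilution_fold: float = 2.0
    n_points: int = 8
    include_zero: bool = True
    duration_s: float = 600.0
    slow_duration_s: float = 7200.0
    sampling_interval_s: float = 1.0
    inter_cycle_gap_s: float = 120.0
    warnings: List[str] = field(default_factory=list)

    def concentrations(self) -> np.ndarray:
        """Descending-order dilution series; a zero point first if requested."""
        n = self.n_points - (1 if self.include_zero else 0)
        series = self.top_conc / self.dilution_fold ** np.arange(n)
        series = series[::-1]  # ascending, weakest first
        if self.include_zero:
            series = np.concatenate([[0.0], series])
        return series

    def time_grid(self, duration: Optional[float] = None) -> np.ndarray:
        d = self.duration_s if duration is None else duration
        return np.arange(0.0, d + 0.5 * self.sampling_interval_s, self.sampling_interval_s)

    def check_coverage(self, fastest_rate: float, duration: Optional[float] = None) -> None:
        """Attach a warning if the phase covers < 3 half-lives at ``fastest_rate``."""
        d = self.duration_s if duration is None else duration
        if fastest_rate > 0 and d < 3.0 * math.log(2.0) / fastest_rate:
            self.warnings.append(
                f"coverage: duration {d:g} s spans < 3 half-lives at rate {fastest_rate:g} s^-1"
            )


def spr_design_for(params: ChipParams, top_conc: float = 2e-6, n_cycles: int = 8) -> ExperimentDesign:
    """Study-condition design for a multi-cycle SPR run against given truth.

    One zero-effector cycle (2 h) anchors the base off-rate, then twofold
    dilutions ascending to ``top_conc``; effector-cycle duration is five
    accelerated half-lives, at least 10 min and at most 2 h, sampled at 1 Hz.
    """
    dur = min(max(600.0, 5.0 * math.log(2.0) / params.k_off_T_HE), 7200.0)
    return ExperimentDesign(
        top_conc=top_conc, dilution_fold=2.0, n_points=n_cycles,
        include_zero=True, duration_s=dur, slow_duration_s=7200.0,
        sampling_interval_s=1.0,
    )


# ---------------------------------------------------------------------------
# SPR cycle sets
# ---------------------------------------------------------------------------

def gen_cycleset(
    params: ChipParams,
    design: ExperimentDesign,
    noise: NoiseModel,
    f_n: Optional[Sequence[float]] = None,
) -> CycleSet:
    """Forward-simulate a multi-cycle sensorgram with host re-loading.

    Ground truth (parameters, per-cycle factors, design, noise) is embedded
    in the CycleSet metadata for recovery scoring.
    """
    concs = design.concentrations()
    n_cyc = concs.size
    f_n = np.ones(n_cyc) if f_n is None else np.asarray(f_n, dtype=float)
    if f_n.size != n_cyc:
        raise ValueError("f_n must have one factor per cycle")
    # coverage is judged at the fastest fitted rate (the accelerated phase);
    # the base rate is anchored by the long zero-effector cycle's slope
    design.check_coverage(params.k_off_T_HE)

    # dry cycles to fix the loading recursion, then sample each phase
    grids = [
        design.time_grid(design.slow_duration_s if c == 0 else None) for c in concs
    ]
    shells = [Cycle(c, g, np.zeros_like(g)) for c, g in zip(concs, grids)]
    initials, _ = propagate_cycles(shells, params)

    rng = noise.rng()
    cycles: List[Cycle] = []
    clean_max = 0.0
    clean: List[np.ndarray] = []
    for c, g, x0, f in zip(concs, grids, initials, f_n):
        traj = chip_trajectory(x0, c, params, g)
        s = response_model(traj, params, f)
        clean.append(s)
        clean_max = max(clean_max, float(np.max(np.abs(s))))
    for c, g, s in zip(concs, grids, clean):
        cycles.append(Cycle(c, g, noise.apply(s, clean_max, rng)))

    truth = {
        "params": params.to_dict(),
        "f_n": f_n.tolist(),
        "fold_acceleration": params.fold_acceleration,
        "noise": {"sigma": noise.sigma, "sigma_frac": noise.sigma_frac, "seed": noise.seed},
        "design_warnings": list(design.warnings),
    }
    return CycleSet(cycles=cycles, inter_cycle_gap_s=design.inter_cycle_gap_s,
                    ground_truth=truth)


# ---------------------------------------------------------------------------
# fluorescence polarization
# ---------------------------------------------------------------------------

def gen_fp_titration(
    K_d: float,
    probe_conc: float,
    P0: float,
    P1: float,
    design: ExperimentDesign,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Equilibrium polarization titration obeying the exact quadratic isotherm.

    Returns a DataFrame with columns ``conc_M`` (host) and ``polarization_mP``;
    ground truth is stored in ``df.attrs``.
    """
    H = design.concentrations()
    P = P0 + P1 * fraction_bound(H, probe_conc, K_d)
    rng = noise.rng()
    P_noisy = noise.apply(P, abs(P1), rng)
    df = pd.DataFrame({"conc_M": H, "polarization_mP": P_noisy})
    df.attrs["ground_truth"] = {"K_d": K_d, "probe_conc": probe_conc, "P0": P0, "P1": P1}
    return df


# ---------------------------------------------------------------------------
# competition / transfer / luminescence time courses
# ---------------------------------------------------------------------------

def gen_competition_courses(
    kind: str,
    params: Dict[str, float],
    design: ExperimentDesign,
    noise: NoiseModel,
    drift: Optional[Dict[str, float]] = None,
) -> List[TimeCourse]:
    """Exponential assay time courses of several flavours.

    ``kind``:

    - ``"forward"``: kinetic competition rises at each effector/target
      concentration, rates from the linear law (needs ``k_on``, ``k_off``).
    - ``"reverse"``: labelled-effector release at each target concentration,
      rates from the hyperbolic reverse law (needs ``k_off_TH_E``,
      ``K_half``, ``k_off_H_E``).
    - ``"chain"``: a single transfer decay (needs ``k_app``), with an
      optional sigmoid baseline drift added; a drift-only reference course
      (zero amplitude) is appended when ``drift`` is given.
    - ``"luminescence"``: sensor activation rise or split-enzyme decay
      (needs ``k_app`` or ``half_time_s``, optional ``direction``).

    ``params`` also takes ``S0`` (baseline) and ``S1`` (amplitude),
    defaulting to 0 and 1.  Ground truth is embedded per-course in metadata.
    """
    S0 = params.get("S0", 0.0)
    S1 = params.get("S1", 1.0)
    rng = noise.rng()
    out: List[TimeCourse] = []

    def make(t, y, meta):
        meta = dict(meta)
        meta["kind"] = kind
        meta["ground_truth"] = dict(params)
        return TimeCourse(t, noise.apply(y, abs(S1), rng), metadata=meta)

    if kind in ("forward", "reverse"):
        concs = design.concentrations()
        for c in concs:
            if kind == "forward":
                k = kapp_linear(c, params["k_on"], params["k_off"])
            else:
                k = kapp_hyperbolic(c, params["k_off_TH_E"], params["K_half"], params["k_off_H_E"])
            # slow wells are followed for longer, up to the slow-phase cap
            dur = min(max(design.duration_s, 5.0 * math.log(2.0) / k), design.slow_duration_s)
            t = design.time_grid(dur)
            if kind == "forward":
                y = S0 + S1 * (1.0 - np.exp(-k * t))
            else:
                y = S0 + S1 * np.exp(-k * t)
            out.append(make(t, y, {"conc_M": float(c), "k_app_true": float(k)}))
        return out

    if kind == "chain":
        k = params["k_app"]
        t = design.time_grid()
        y = S0 + S1 * np.exp(-k * t)
        if drift:
            d = sigmoid_drift(t, drift["S0"], drift["S1"], drift["k"], drift["t_half"])
            out.append(make(t, y + d - S0, {"role": "sample", "k_app_true": k}))
            ref = TimeCourse(t, noise.apply(d, abs(S1), rng),
                             metadata={"role": "reference", "kind": kind,
                                       "drift_truth": dict(drift)})
            out.append(ref)
        else:
            out.append(make(t, y, {"role": "sample", "k_app_true": k}))
        return out

    if kind == "luminescence":
        k = params.get("k_app")
        if k is None:
            k = math.log(2.0) / params["half_time_s"]
        direction = params.get("direction", "rise")
        t = design.time_grid()
        if direction == "rise":
            y = S0 + S1 * (1.0 - np.exp(-k * t))
        else:
            y = S0 + S1 * np.exp(-k * t)
        out.append(make(t, y, {"direction": direction, "k_app_true": float(k)}))
        return out

    raise ValueError(f"unknown kind {kind!r}")


def gen_association_courses(
    topology,
    rates,
    design: ExperimentDesign,
    noise: NoiseModel,
    n_times: int = 150,
) -> List[TimeCourse]:
    """Effector-association time courses at each effector concentration.

    Emulates the ternary-formation experiment: host pre-saturated with
    target on the chip, effector flowed at one concentration per course
    under constant excess target, so only effector binding is observed.
    The excess target keeps the host loaded, which is modelled by zeroing
    the target-release channels; the trajectory of the effector-bound
    fraction is then fitted elsewhere with a single-exponential rise to
    give the apparent on-rate at each concentration.

    A flexible (induced-fit) effector yields a linear k_app vs [E] series;
    a rigid (conformational-selection) effector yields a hyperbolic series
    saturating at the switch rate.
    """
    from .laws import kapp_conformational_selection
    from .network import build_network, simulate
    from .rates import MechanismTopology, RateConstantSet

    topology = MechanismTopology(topology)
    clamped = RateConstantSet(**{
        **{k: v for k, v in rates.to_dict()["rates"].items()},
        "k_off_TH": 0.0, "k_off_THE_toT": 0.0,
    })
    net = build_network(topology, clamped)
    rng = noise.rng()
    out: List[TimeCourse] = []
    concs = design.concentrations()
    concs = concs[concs > 0]
    for E in concs:
        if topology is MechanismTopology.INDUCED_FIT:
            k_expected = kapp_linear(E, rates.k_on_THE_viaE, rates.k_off_THE_toE)
        else:
            k_expected = kapp_conformational_selection(
                E, rates.k_switch, rates.k_unswitch,
                rates.k_on_THE_viaE, rates.k_off_THE_toE,
            )
        t = np.linspace(0.0, 5.0 / k_expected, n_times)
        h0 = E / 1000.0  # pseudo-first-order: effector in large excess
        traj = simulate(net, {"TH_X": h0, "E": E}, t)
        y = traj["THE"] / h0
        out.append(TimeCourse(
            t, noise.apply(y, 1.0, rng),
            metadata={"conc_M": float(E), "k_app_expected": float(k_expected),
                      "topology": topology.value},
        ))
    return out


def gen_decay_trace(
    rate: float,
    noise: NoiseModel,
    n_half_lives: float = 5.0,
    sampling_interval_s: float = 1.0,
    S0: float = 0.0,
    S1: float = 1.0,
) -> TimeCourse:
    """A first-order dissociation trace over ``n_half_lives`` half-lives."""
    t_end = n_half_lives * math.log(2.0) / rate
    t = np.arange(0.0, t_end + 0.5 * sampling_interval_s, sampling_interval_s)
    y = S0 + S1 * np.exp(-rate * t)
    return TimeCourse(t, noise.apply(y, abs(S1), noise.rng()),
                      metadata={"k_true": rate, "kind": "decay"})


# ---------------------------------------------------------------------------
# determinism helpers
# ---------------------------------------------------------------------------

def checksum_arrays(*arrays: np.ndarray) -> str:
    """SHA-256 over the exact bytes of float64 views of the arrays."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
    return h.hexdigest()


def cycleset_checksum(cs: CycleSet) -> str:
    return checksum_arrays(*[c.times for c in cs.cycles], *[c.signal for c in cs.cycles])
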