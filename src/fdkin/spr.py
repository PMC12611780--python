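"""Multi-cycle SPR model of facilitated dissociation on the chip.

The chip carries target sites that are loaded with host at the start of each
cycle; dissociation is then monitored under flow of effector at one
concentration per cycle.  Three chip populations are tracked as
dimensionless fractions of total sites:

- ``TH``  responsive target-host complex,
- ``THE`` strained ternary complex (effector bound),
- ``THn`` target bound to effector-unresponsive host, which accumulates
  across cycles because a fraction ``1 - f_responsive`` of freshly loaded
  host does not respond to the effector.

Within a dissociation phase the effector concentration is constant, so the
chip ODE is linear and is propagated exactly through its eigen-decomposition
(tests cross-check against a numeric ODE solver).  The model is fitted
globally across all cycles; the effective facilitated-dissociation rate
``k_eff([E])`` is then extracted from the half-time of total bound target in
the simplified two-species system, and summarized with a constrained
hyperbolic fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares

from .fitting import DoseResponseSeries, FitFailureError, fit_dose_response, fit_single_exponential
from .timecourse import TimeCourse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChipParams:
    """Rate constants, responsive fraction and response amplitudes of the chip model.

    Rates are s^-1 except ``k_on_TH_E`` (M^-1 s^-1); amplitudes are response
    units per unit chip fraction.
    """

    k_off_T_H: float
    k_off_T_HE: float
    k_on_TH_E: float
    k_off_TH_E: float
    k_off_T_Hn: float
    f_responsive: float = 1.0
    a_TH: float = 1.0
    a_THE: float = 1.0
    a_THn: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.f_responsive <= 1.0:
            raise ValueError("f_responsive must be in [0, 1]")
        for name in ("k_off_T_H", "k_off_T_HE", "k_on_TH_E", "k_off_TH_E",
                     "k_off_T_Hn", "a_TH", "a_THE", "a_THn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def fold_acceleration(self) -> float:
        """Headline figure of merit: k_off_T_HE / k_off_T_H."""
        return self.k_off_T_HE / self.k_off_T_H

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cycle:
    """One dissociation phase: effector concentration plus its time course."""

    effector_conc: float
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.effector_conc < 0:
            raise ValueError("effector_conc must be >= 0")

    def timecourse(self) -> TimeCourse:
        return TimeCourse(self.times, self.signal,
                          metadata={"conc_M": self.effector_conc, "phase": "dissociation"})


@dataclass
class CycleSet:
    """Ordered SPR cycles (order matters: unresponsive host accumulates)."""

    cycles: List[Cycle]
    inter_cycle_gap_s: float = 120.0
    ground_truth: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.effector_conc for c in self.cycles])


@dataclass
class GlobalFitResult:
    """Jointly fitted chip parameters with per-cycle diagnostics."""

    params: ChipParams
    f_n: np.ndarray
    residual_rms: np.ndarray
    objective: float
    cov: Optional[np.ndarray]
    free_names: List[str]
    success: bool
    warnings: List[str] = field(default_factory=list)

    @property
    def fold_acceleration(self) -> float:
        return self.params.fold_acceleration

    def fold_acceleration_ci(self, z: float = 2.0) -> Tuple[float, float]:
        """Approximate confidence interval for the fold acceleration.

        Propagates the joint covariance of log10(k_off_T_HE) and
        log10(k_off_T_H); returns a degenerate interval when either rate was
        fixed or the covariance is unavailable.
        """
        fold = self.fold_acceleration
        if self.cov is None or not {"k_off_T_H", "k_off_T_HE"} <= set(self.free_names):
            return (fold, fold)
        i = self.free_names.index("k_off_T_HE")
        j = self.free_names.index("k_off_T_H")
        var = self.cov[i, i] + self.cov[j, j] - 2.0 * self.cov[i, j]
        if var <= 0:
            return (fold, fold)
        half = z * math.sqrt(var)
        d = math.log10(fold)
        return (10.0 ** (d - half), 10.0 ** (d + half))


# ---------------------------------------------------------------------------
# chip ODE and exact propagation
# ---------------------------------------------------------------------------

def chip_ode_rhs(state: Sequence[float], E_conc: float, params: ChipParams) -> np.ndarray:
    """d/dt of ``[THE, TH, THn]`` on the chip at effector concentration ``E``."""
    THE, TH, THn = state
    p = params
    dTHE = -p.k_off_T_HE * THE + p.k_on_TH_E * TH * E_conc - p.k_off_TH_E * THE
    dTH = -p.k_off_T_H * TH - p.k_on_TH_E * TH * E_conc + p.k_off_TH_E * THE
    dTHn = -p.k_off_T_Hn * THn
    return np.array([dTHE, dTH, dTHn])


def _two_state_matrix(params: ChipParams, E_conc: float) -> np.ndarray:
    """Rate matrix of the coupled [THE, TH] block (THn is decoupled)."""
    p = params
    return np.array([
        [-(p.k_off_T_HE + p.k_off_TH_E), p.k_on_TH_E * E_conc],
        [p.k_off_TH_E, -(p.k_off_T_H + p.k_on_TH_E * E_conc)],
    ])


def _propagate_linear(M: np.ndarray, x0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact solution x(t) = e^{M t} x0 for a real-eigenvalue 2x2 system."""
    # degenerate eigenvalues only at measure-zero parameter points; nudge
    a, d = M[0, 0], M[1, 1]
    disc = (a - d) ** 2 + 4.0 * M[0, 1] * M[1, 0]
    if disc < 1e-24 * max(a * a + d * d, 1e-300):
        M = M.copy()
        M[0, 0] = a * (1 + 1e-8) - 1e-30
    w, V = np.linalg.eig(M)
    w, V = w.real, V.real
    c0 = np.linalg.solve(V, x0)
    return V @ (c0[:, None] * np.exp(w[:, None] * t[None, :]))


def chip_trajectory(
    x0: Sequence[float], E_conc: float, params: ChipParams, t: np.ndarray
) -> np.ndarray:
    """Chip fractions ``[THE, TH, THn]`` over a dissociation phase (exact).

    ``t`` is time since the start of the phase; ``[E]`` is constant under
    flow.  Returns an array of shape (3, len(t)).
    """
    t = np.asarray(t, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    out = np.empty((3, t.size))
    out[:2] = _propagate_linear(_two_state_matrix(params, E_conc), x0[:2], t)
    out[2] = x0[2] * np.exp(-params.k_off_T_Hn * t)
    return out


def propagate_cycles(
    cycles: CycleSet | Sequence[Cycle], params: ChipParams
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Initial and final chip states per cycle under the loading recursion.

    Before cycle n the chip is re-loaded with host: free sites from the end
    of cycle n-1 are filled, a fraction ``f_responsive`` responsively.  Any
    ternary complex left at the end of a cycle is counted as free sites (the
    model assumes the effector-bound state has cleared between cycles; a
    warning is attached by :func:`global_fit` when that assumption is dubious).
    """
    cyc = cycles.cycles if isinstance(cycles, CycleSet) else list(cycles)
    TH_final = 0.0
    THn_final = 0.0
    initials: List[np.ndarray] = []
    finals: List[np.ndarray] = []
    for cycle in cyc:
        T_free = 1.0 - TH_final - THn_final
        x0 = np.array([
            0.0,
            TH_final + params.f_responsive * T_free,
            THn_final + (1.0 - params.f_responsive) * T_free,
        ])
        initials.append(x0)
        dt_end = np.array([cycle.times[-1] - cycle.times[0]])
        xf = chip_trajectory(x0, cycle.effector_conc, params, dt_end)[:, 0]
        finals.append(xf)
        TH_final, THn_final = float(xf[1]), float(xf[2])
    return initials, finals


def response_model(
    trajectory: np.ndarray, params: ChipParams, f_n: float = 1.0
) -> np.ndarray:
    """SPR response ``S = f_n (a_TH [TH] + a_THE [THE] + a_THn [THn])``."""
    THE, TH, THn = trajectory
    return f_n * (params.a_TH * TH + params.a_THE * THE + params.a_THn * THn)


def model_cycleset(cycles: CycleSet, params: ChipParams, f_n: Sequence[float]) -> List[np.ndarray]:
    """Predicted response per cycle for the full multi-cycle model."""
    initials, _ = propagate_cycles(cycles, params)
    out = []
    for cycle, x0, f in zip(cycles.cycles, initials, f_n):
        traj = chip_trajectory(x0, cycle.effector_conc, params,
                               cycle.times - cycle.times[0])
        out.append(response_model(traj, params, f))
    return out


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

#: log10 bounds for the rate parameters; off-rates span the measurable range
_RATE_BOUNDS = {
    "k_off_T_H": (-7.0, 0.0),
    "k_off_T_HE": (-7.0, 0.0),
    "k_on_TH_E": (2.0, 7.0),
    "k_off_TH_E": (-7.0, 0.0),
    "k_off_T_Hn": (-7.0, 0.0),
}
_F_RESP_BOUNDS = (0.5, 1.0)
_AMP_BOUNDS = (0.01, 10.0)
_FN_BOUNDS = (0.5, 2.0)

_RATE_NAMES = list(_RATE_BOUNDS)
_AMP_NAMES = ["a_TH", "a_THE", "a_THn"]


def _default_init(cycles: CycleSet) -> Dict[str, float]:
    """Data-driven starting point from per-cycle single-exponential fits."""
    kapps, concs = [], []
    for cycle in cycles.cycles:
        try:
            res = fit_single_exponential(cycle.timecourse())
            kapps.append(res.reported_rate)
            concs.append(cycle.effector_conc)
        except FitFailureError:
            continue
    kapps = np.asarray(kapps)
    concs = np.asarray(concs)
    if kapps.size == 0:
        kapps = np.array([1e-3])
        concs = np.array([0.0])
    k_fast = float(np.max(kapps))
    k_slow = float(np.min(kapps))
    k_off_TH_E0 = 1e-3
    # crude K_half estimate from a hyperbolic fit of the per-cycle rates
    k_on0 = 1e5
    pos = concs > 0
    if pos.sum() >= 4:
        try:
            hyp = fit_dose_response(concs[pos], kapps[pos], "hyperbolic")
            k_on0 = (k_fast + k_off_TH_E0) / hyp.params["K_half"]
        except FitFailureError:
            pass
    return {
        "k_off_T_H": k_slow,
        "k_off_T_HE": k_fast,
        "k_on_TH_E": min(max(k_on0, 1e3), 1e7),
        "k_off_TH_E": k_off_TH_E0,
        "k_off_T_Hn": k_slow,
        "f_responsive": 0.9,
        "a_TH": 1.0, "a_THE": 1.0, "a_THn": 1.0,
    }


def global_fit(
    cycles: CycleSet,
    fixed: Optional[Dict[str, float]] = None,
    init: Optional[Dict[str, float]] = None,
) -> GlobalFitResult:
    """Globally fit the multi-cycle chip model to all dissociation curves.

    All rate constants, ``f_responsive``, the three response amplitudes and
    the per-cycle amplitude factors ``f_n`` (n >= 2; ``f_1`` is fixed to 1
    to anchor the response scale) are varied jointly; only dissociation
    curves enter the objective, equally weighted.  ``fixed`` pins named
    parameters (e.g. ``{"f_responsive": 1.0}``); ``init`` overrides the
    data-driven starting point.
    """
    n_cyc = len(cycles)
    if n_cyc < 1:
        raise ValueError("empty cycle set")
    concs = cycles.concentrations
    pos = concs[concs > 0]
    if n_cyc >= 4 and pos.size >= 2 and pos.max() / pos.min() < 8:
        logger.warning("effector concentrations span < 8-fold; fit may be poorly constrained")

    fixed = dict(fixed or {})
    start = _default_init(cycles)
    start.update(init or {})

    free_names: List[str] = []
    x0, lb, ub = [], [], []

    def add(name, value, bounds, log=False):
        if name in fixed:
            return
        free_names.append(name)
        if log:
            x0.append(math.log10(min(max(value, 10 ** bounds[0]), 10 ** bounds[1])))
        else:
            x0.append(min(max(value, bounds[0]), bounds[1]))
        lb.append(bounds[0])
        ub.append(bounds[1])

    for name in _RATE_NAMES:
        add(name, start[name], _RATE_BOUNDS[name], log=True)
    add("f_responsive", start["f_responsive"], _F_RESP_BOUNDS)
    for name in _AMP_NAMES:
        add(name, start[name], _AMP_BOUNDS)
    for i in range(1, n_cyc):  # f_1 anchored to 1
        add(f"f_{i + 1}", 1.0, _FN_BOUNDS)

    data = [c.signal for c in cycles.cycles]
    scale = max(float(np.max(np.abs(np.concatenate(data)))), 1e-12)

    def unpack(x) -> Tuple[ChipParams, np.ndarray]:
        vals = dict(fixed)
        for name, v in zip(free_names, x):
            if name in _RATE_BOUNDS:
                vals[name] = 10.0 ** v
            else:
                vals[name] = float(v)
        f_n = np.ones(n_cyc)
        for i in range(1, n_cyc):
            key = f"f_{i + 1}"
            if key in vals:
                f_n[i] = vals.pop(key)
        params = ChipParams(**{k: vals[k] for k in _RATE_NAMES + ["f_responsive"] + _AMP_NAMES})
        return params, f_n

    def resid(x):
        params, f_n = unpack(x)
        pred = model_cycleset(cycles, params, f_n)
        return np.concatenate([(p - d) for p, d in zip(pred, data)]) / scale

    sol = least_squares(
        resid, np.array(x0), bounds=(np.array(lb), np.array(ub)),
        x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=4000,
    )
    params, f_n = unpack(sol.x)
    pred = model_cycleset(cycles, params, f_n)
    per_cycle_rms = np.array([
        float(np.sqrt(np.mean((p - d) ** 2))) for p, d in zip(pred, data)
    ])
    objective = float(np.sum(sol.fun ** 2))

    warnings_out = [
        "weak_identifiability: (k_on_TH_E, k_off_TH_E) tightly covary and are "
        "not individually determined by dissociation data"
    ]
    if params.k_off_TH_E * cycles.inter_cycle_gap_s < 3.0:
        warnings_out.append(
            "slow_ternary_clearance: fitted k_off_TH_E times the inter-cycle gap "
            "is < 3, so the assumption of zero ternary complex at cycle start "
            "may be invalid"
        )

    try:
        # covariance of the free parameter vector (log10 units for rates),
        # from the Jacobian of the scale-normalized residuals
        dof = max(sum(d.size for d in data) - len(free_names), 1)
        cov = objective / dof * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        cov = None
        warnings_out.append("singular_jacobian: covariance unavailable")

    if not sol.success:
        raise FitFailureError(
            f"global fit did not converge: {sol.message}",
            {"params": params.to_dict(), "per_cycle_rms": per_cycle_rms.tolist()},
        )
    logger.info("global fit converged: objective=%.4g nfev=%d fold=%.3g",
                objective, sol.nfev, params.fold_acceleration)
    return GlobalFitResult(
        params=params, f_n=f_n, residual_rms=per_cycle_rms, objective=objective,
        cov=cov, free_names=free_names, success=True, warnings=warnings_out,
    )


# ---------------------------------------------------------------------------
# effective rate and summary
# ---------------------------------------------------------------------------

def compute_keff(params: ChipParams, E_conc: float, horizon_cap: float = 1e12) -> float:
    """Effective facilitated-dissociation rate constant at one effector concentration.

    Solves the simplified two-species system (no unresponsive host) from
    ``[TH] = 1, [THE] = 0`` for the half-time of total bound target,
    ``[THE](t_half) + [TH](t_half) = 0.5``, and returns ``ln 2 / t_half``.
    """
    M = _two_state_matrix(params, E_conc)
    x0 = np.array([0.0, 1.0])

    def bound(t: float) -> float:
        return float(np.sum(_propagate_linear(M, x0, np.array([t]))))

    # bracket the half-time, extending the horizon geometrically
    t_hi = math.log(2.0) / max(params.k_off_T_HE, params.k_off_T_H, 1e-300)
    while bound(t_hi) > 0.5:
        t_hi *= 4.0
        if t_hi > horizon_cap:
            raise FitFailureError(f"half-time beyond integration horizon ({horizon_cap:g} s)")
    t_lo = t_hi / 4.0
    while bound(t_lo) < 0.5:
        t_lo /= 4.0
        if t_lo < 1e-30:
            raise FitFailureError("half-time vanishes; check parameters")
    t_half = brentq(lambda t: bound(t) - 0.5, t_lo, t_hi, rtol=1e-12, xtol=1e-300)
    return math.log(2.0) / t_half


def summarize_fd(
    params: ChipParams, E_grid: Sequence[float]
) -> Tuple[DoseResponseSeries, float]:
    """k_eff over an effector grid plus the constrained hyperbolic summary.

    The hyperbolic fit holds the plateau at ``k_off_T_HE`` and the baseline
    at ``k_off_T_H`` (both from the global fit) and fits only ``K_half``.
    Returns the series and the fold acceleration ``k_off_T_HE / k_off_T_H``.
    """
    E = np.asarray(E_grid, dtype=float)
    keff = np.array([compute_keff(params, e) for e in E])
    series = fit_dose_response(
        E, keff, "hyperbolic",
        fixed={"k_max": params.k_off_T_HE - params.k_off_T_H,
               "k_base": params.k_off_T_H},
    )
    return series, params.fold_acceleration
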