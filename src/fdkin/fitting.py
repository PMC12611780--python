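"""Nonlinear least-squares fitting of closed-form kinetic models.

Exponential time-course fits use variable projection: the decay rate(s) are
optimized in log space (positivity for free) while the baseline and
amplitudes, which enter linearly, are solved exactly by linear least squares
at each rate evaluation.  This makes the fits fast and robust to poor
amplitude initialization, and a multi-start over log-spaced rate seeds
guards against local optima.

Dose-response fits cover the three rate laws used for apparent/effective
rate constants (linear, hyperbolic, conformational-selection relaxation),
with optional parameter fixing for constrained summary fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .laws import fraction_bound, kapp_conformational_selection, kapp_hyperbolic, kapp_linear
from .timecourse import TimeCourse

logger = logging.getLogger(__name__)

#: default multi-start rate seeds, s^-1 (log-spaced; overridable per call)
DEFAULT_RATE_SEEDS = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)

#: amplitude share above which the faster double-exponential component is reported
FAST_AMPLITUDE_SHARE = 0.30


class FitFailureError(RuntimeError):
    """A fit did not converge or the data cannot constrain the model."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class ExponentialFitResult:
    """Result of a single or double exponential fit.

    ``rates`` is sorted fastest-first; ``reported_rate`` follows the
    selection rule recorded in ``selection_rule``.
    """

    s0: float
    amplitudes: Tuple[float, ...]
    rates: Tuple[float, ...]
    reported_rate: float
    rms: float
    cov: Optional[np.ndarray]
    direction: str = "decay"
    n_components: int = 1
    selection_rule: str = "single"
    warnings: List[str] = field(default_factory=list)

    @property
    def half_time(self) -> float:
        """ln 2 over the reported rate."""
        return math.log(2.0) / self.reported_rate


@dataclass
class DoseResponseSeries:
    """(concentration, apparent rate) pairs plus the law fitted to them."""

    concentrations: np.ndarray
    k_app: np.ndarray
    law: str
    params: Dict[str, float]
    cov: Optional[np.ndarray] = None
    rms: float = float("nan")
    aicc: float = float("nan")
    warnings: List[str] = field(default_factory=list)

    def predict(self, conc) -> np.ndarray:
        p = self.params
        if self.law == "linear":
            return kapp_linear(conc, p["k_on"], p["k_off"])
        if self.law == "hyperbolic":
            return kapp_hyperbolic(conc, p["k_max"], p["K_half"], p["k_base"])
        if self.law == "conformational_selection":
            return kapp_conformational_selection(
                conc, p["k_switch"], p["k_unswitch"], p["k_on"], p["k_off"]
            )
        raise ValueError(f"unknown law {self.law!r}")


@dataclass
class IsothermFitResult:
    """Equilibrium titration fit; tight binding reported as an upper bound."""

    K_d: float
    P0: float
    P1: float
    probe_conc: float
    tight_binding: bool
    rms: float
    cov: Optional[np.ndarray] = None
    warnings: List[str] = field(default_factory=list)

    @property
    def reported_affinity(self) -> str:
        if self.tight_binding:
            return f"K_d < {self.probe_conc:g} M"
        return f"K_d = {self.K_d:g} M"


# ---------------------------------------------------------------------------
# exponential fits (variable projection over log-rates)
# ---------------------------------------------------------------------------

def _exp_basis(tau: np.ndarray, rates: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(tau)] + [np.exp(-k * tau) for k in rates]
    return np.column_stack(cols)


def _varpro_objective(tau: np.ndarray, y: np.ndarray, rates: Sequence[float]):
    """Solve linear coefficients for fixed rates; return (residuals, coeffs)."""
    A = _exp_basis(tau, rates)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef - y, coef


def _multistart_logk(tau, y, seeds_list, n_rates):
    """Run VarPro least-squares from each seed; return best + all objectives."""
    best = None
    objectives = []
    for seeds in seeds_list:
        x0 = np.log(np.asarray(seeds, dtype=float))

        def resid(x):
            r, _ = _varpro_objective(tau, y, np.exp(x))
            return r

        try:
            sol = least_squares(resid, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - defensive
            continue
        obj = float(np.sum(sol.fun ** 2))
        objectives.append(obj)
        if best is None or obj < best[0]:
            best = (obj, np.exp(sol.x))
    if best is None:
        raise FitFailureError("all multi-start fits failed")
    return best, objectives


def _check_multistart(objectives: List[float], warnings_out: List[str]) -> None:
    if not objectives:
        return
    best = min(objectives)
    scale = best + 1e-300
    agree = sum(1 for o in objectives if (o - best) / scale < 1e-6)
    if agree < len(objectives):
        warnings_out.append("multistart_divergent: local optima detected across rate seeds")


def _exp_covariance(tau, y, coef, rates, direction):
    """Jacobian-based covariance in (S0, S1[, S2], k1[, k2]) order."""
    n = tau.size
    p = 1 + 2 * len(rates)
    if n <= p:
        return None
    cols = [np.ones_like(tau)]
    for k in rates:
        cols.append(np.exp(-k * tau))
    for amp, k in zip(coef[1:], rates):
        cols.append(-amp * tau * np.exp(-k * tau))
    J = np.column_stack(cols)
    resid, _ = _varpro_objective(tau, y, rates)
    sigma2 = float(np.sum(resid ** 2)) / (n - p)
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None
    return cov


def _prepare(tc: TimeCourse, min_points: int):
    if len(tc) < min_points:
        raise FitFailureError(f"need >= {min_points} points, got {len(tc)}")
    tau = tc.times - tc.t0
    return tau, tc.signal.astype(float)


def fit_single_exponential(
    tc: TimeCourse,
    direction: str = "decay",
    rate_seeds: Iterable[float] = DEFAULT_RATE_SEEDS,
) -> ExponentialFitResult:
    """Fit ``S0 + S1 e^{-k (t - t0)}`` (decay) or ``S0 + S1 (1 - e^{-k(t-t0)})`` (rise).

    The rate is estimated by variable projection over log k from multiple
    seeds; amplitudes indistinguishable from the residual noise raise
    :class:`FitFailureError`.
    """
    if direction not in ("decay", "rise"):
        raise ValueError("direction must be 'decay' or 'rise'")
    tau, y = _prepare(tc, 8)
    if np.ptp(y) == 0:
        raise FitFailureError("constant signal: amplitude indistinguishable from zero")

    seeds = sorted(set(rate_seeds))
    span = tau[-1] - tau[0]
    seeds_list = [(s,) for s in seeds] + [(3.0 / span,)]
    (obj, rates), objectives = _multistart_logk(tau, y, seeds_list, 1)
    warnings_out: List[str] = []
    _check_multistart(objectives, warnings_out)

    k = float(rates[0])
    resid, coef = _varpro_objective(tau, y, rates)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    c0, c1 = float(coef[0]), float(coef[1])
    # basis coefficient c1 multiplies e^{-k tau}; interpret per direction
    if direction == "decay":
        s0, s1 = c0, c1
    else:
        s0, s1 = c0 + c1, -c1
    if abs(c1) < 2.0 * rms:
        raise FitFailureError(
            "amplitude indistinguishable from zero",
            {"amplitude": c1, "rms": rms},
        )
    cov = _exp_covariance(tau, y, coef, rates, direction)
    logger.debug("single-exp fit: k=%.4g rms=%.3g obj=%.3g", k, rms, obj)
    return ExponentialFitResult(
        s0=s0, amplitudes=(s1,), rates=(k,), reported_rate=k, rms=rms,
        cov=cov, direction=direction, n_components=1,
        selection_rule="single", warnings=warnings_out,
    )


def fit_double_exponential(
    tc: TimeCourse,
    rate_seeds: Iterable[float] = DEFAULT_RATE_SEEDS,
) -> ExponentialFitResult:
    """Fit ``S0 + S1 e^{-k1 tau} + S2 e^{-k2 tau}`` with k1 >= k2.

    The reported rate follows the faster-and-higher-amplitude rule: the
    faster component is reported when its amplitude share is at least
    :data:`FAST_AMPLITUDE_SHARE`, otherwise the larger-amplitude component.
    Indistinguishable components (rate ratio < 3 or amplitude ratio > 20)
    degrade the fit to a single exponential with a warning.
    """
    tau, y = _prepare(tc, 16)
    if np.ptp(y) == 0:
        raise FitFailureError("constant signal: amplitude indistinguishable from zero")

    seeds = sorted(set(rate_seeds))
    pairs = [(a, b) for i, a in enumerate(seeds) for b in seeds[i + 1:]]
    # anchor around a single-exponential estimate as well
    try:
        single = fit_single_exponential(tc, "decay", rate_seeds)
        k1 = single.rates[0]
        pairs += [(k1 * 5.0, k1 / 5.0), (k1 * 20.0, k1)]
    except FitFailureError:
        single = None
    (obj, rates), objectives = _multistart_logk(tau, y, pairs, 2)
    warnings_out: List[str] = []
    _check_multistart(objectives, warnings_out)

    resid, coef = _varpro_objective(tau, y, rates)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    # order components fastest first
    order = np.argsort(rates)[::-1]
    k_fast, k_slow = float(rates[order[0]]), float(rates[order[1]])
    a_fast, a_slow = float(coef[1 + order[0]]), float(coef[1 + order[1]])

    amp_tot = abs(a_fast) + abs(a_slow)
    ratio_rate = k_fast / max(k_slow, 1e-300)
    ratio_amp = (max(abs(a_fast), abs(a_slow)) / max(min(abs(a_fast), abs(a_slow)), 1e-300))
    if ratio_rate < 3.0 or ratio_amp > 20.0:
        res = fit_single_exponential(tc, "decay", rate_seeds)
        res.warnings.append(
            f"degraded_to_single: components indistinguishable "
            f"(rate ratio {ratio_rate:.3g}, amplitude ratio {ratio_amp:.3g})"
        )
        res.selection_rule = "degraded_to_single"
        logger.warning("double-exp fit degraded to single (rate ratio %.3g, amp ratio %.3g)",
                       ratio_rate, ratio_amp)
        return res

    if amp_tot == 0:
        raise FitFailureError("amplitudes indistinguishable from zero")
    share_fast = abs(a_fast) / amp_tot
    if share_fast >= FAST_AMPLITUDE_SHARE:
        reported = k_fast
        rule = f"faster (amplitude share {share_fast:.2f} >= {FAST_AMPLITUDE_SHARE})"
    else:
        reported = k_fast if abs(a_fast) > abs(a_slow) else k_slow
        rule = f"larger amplitude (fast share {share_fast:.2f} < {FAST_AMPLITUDE_SHARE})"

    cov = _exp_covariance(tau, y, coef, rates, "decay")
    return ExponentialFitResult(
        s0=float(coef[0]), amplitudes=(a_fast, a_slow), rates=(k_fast, k_slow),
        reported_rate=reported, rms=rms, cov=cov, direction="decay",
        n_components=2, selection_rule=rule, warnings=warnings_out,
    )


# ---------------------------------------------------------------------------
# dose-response fits
# ---------------------------------------------------------------------------

_LAW_PARAMS = {
    "linear": ("k_on", "k_off"),
    "hyperbolic": ("k_max", "K_half", "k_base"),
    "conformational_selection": ("k_switch", "k_unswitch", "k_on", "k_off"),
}

#: box bound applied to k_off in the conformational-selection law fit
CS_KOFF_MAX = 1e-4


def _aicc(n: int, rss: float, p: int) -> float:
    if n <= p + 1:
        return float("inf")
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * p
    return aic + 2 * p * (p + 1) / (n - p - 1)


def _dose_weights(k: np.ndarray, weighting: str) -> np.ndarray:
    """Per-point weights: uniform, or inverse-rate (variance-stabilizing
    when rate errors scale with the rate, as they do for rates spanning
    decades)."""
    k_scale = max(float(np.max(np.abs(k))), 1e-300)
    if weighting == "absolute":
        return np.full_like(k, 1.0 / k_scale)
    if weighting == "relative":
        return 1.0 / np.maximum(np.abs(k), 1e-6 * k_scale)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_dose_response(
    concentrations: Sequence[float],
    k_app: Sequence[float],
    law: str,
    fixed: Optional[Dict[str, float]] = None,
    weighting: str = "relative",
) -> DoseResponseSeries:
    """Fit a rate law to (concentration, apparent rate) pairs.

    ``fixed`` maps parameter names to externally supplied values, e.g. the
    constrained hyperbolic summary fit holds ``k_max`` and ``k_base`` at the
    global-fit off-rates and fits only ``K_half``.  Rate and K parameters
    are optimized in log space.  Residuals are inverse-rate weighted by
    default (``weighting="relative"``) so that points spanning decades of
    rate contribute comparably; pass ``"absolute"`` for unweighted fitting.
    """
    c = np.asarray(concentrations, dtype=float)
    k = np.asarray(k_app, dtype=float)
    if c.shape != k.shape or c.ndim != 1:
        raise ValueError("concentrations and k_app must be 1-D arrays of equal length")
    if np.unique(c).size != c.size:
        raise ValueError("concentrations must be distinct")
    if law not in _LAW_PARAMS:
        raise ValueError(f"unknown law {law!r}")
    fixed = dict(fixed or {})
    names = _LAW_PARAMS[law]
    free = [n for n in names if n not in fixed]
    min_pts = 4 if law in ("hyperbolic", "conformational_selection") else len(free) + 1
    if c.size < max(min_pts, len(free) + 1):
        raise FitFailureError(f"need >= {max(min_pts, len(free) + 1)} distinct concentrations for {law}")
    warnings_out: List[str] = []

    W = _dose_weights(k, weighting)

    if law == "linear" and not fixed:
        A = np.column_stack([c, np.ones_like(c)])
        coef, *_ = np.linalg.lstsq(A * W[:, None], k * W, rcond=None)
        resid = A @ coef - k
        rss_w = float(np.sum((resid * W) ** 2))
        dof = max(c.size - 2, 1)
        Aw = A * W[:, None]
        cov = rss_w / dof * np.linalg.inv(Aw.T @ Aw)
        params = {"k_on": float(coef[0]), "k_off": float(coef[1])}
        return DoseResponseSeries(
            concentrations=c, k_app=k, law=law, params=params, cov=cov,
            rms=float(np.sqrt(np.mean(resid ** 2))), aicc=_aicc(c.size, rss_w, 2),
            warnings=warnings_out,
        )

    # nonlinear laws: log-space optimization with multi-start
    pos = np.sort(c[c > 0])
    c_mid = pos[pos.size // 2] if pos.size else 1e-9
    c_max = pos[-1] if pos.size else 1e-6
    k_scale = max(float(np.max(np.abs(k))), 1e-12)

    def model(p: Dict[str, float]):
        if law == "linear":
            return kapp_linear(c, p["k_on"], p["k_off"])
        if law == "hyperbolic":
            return kapp_hyperbolic(c, p["k_max"], p["K_half"], p["k_base"])
        return kapp_conformational_selection(
            c, p["k_switch"], p["k_unswitch"], p["k_on"], p["k_off"]
        )

    lo = {"k_max": 1e-9, "K_half": 1e-13, "k_base": 1e-12, "k_switch": 1e-7,
          "k_unswitch": 1e-7, "k_on": 1e1, "k_off": 1e-9}
    hi = {"k_max": 1e3, "K_half": 1.0, "k_base": 1e2, "k_switch": 1e2,
          "k_unswitch": 1e4, "k_on": 1e9, "k_off": CS_KOFF_MAX}

    if law == "hyperbolic":
        starts = [
            {"k_max": k_scale, "K_half": kh, "k_base": max(float(np.min(k)), 1e-9)}
            for kh in (c_mid / 4, c_mid, c_mid * 4, c_max)
        ]
    elif law == "conformational_selection":
        k_sat = k_scale
        starts = [
            {"k_switch": k_sat, "k_unswitch": k_sat * r, "k_on": kon, "k_off": 1e-5}
            for r in (3.0, 10.0, 30.0)
            for kon in (k_sat / c_mid, 10 * k_sat / c_mid)
        ]
    else:  # linear with fixed params
        starts = [{"k_on": k_scale / c_max, "k_off": max(float(np.min(k)), 1e-12)}]

    best = None
    objectives = []
    for start in starts:
        x0 = np.array([math.log(min(max(start[n], lo[n]), hi[n])) for n in free])
        lb = np.array([math.log(lo[n]) for n in free])
        ub = np.array([math.log(hi[n]) for n in free])
        x0 = np.clip(x0, lb, ub)

        def resid(x):
            p = dict(fixed)
            p.update({n: math.exp(v) for n, v in zip(free, x)})
            return (model(p) - k) * W

        sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        obj = float(np.sum(sol.fun ** 2))
        objectives.append(obj)
        if best is None or obj < best[0]:
            best = (obj, sol)
    _check_multistart(objectives, warnings_out)
    obj, sol = best
    params = dict(fixed)
    params.update({n: math.exp(v) for n, v in zip(free, sol.x)})
    resid_abs = (model(params) - k)
    rss_w = float(np.sum((resid_abs * W) ** 2))
    # covariance of the free log-parameters
    dof = max(c.size - len(free), 1)
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = rss_w / dof * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = None
        warnings_out.append("singular_jacobian: covariance unavailable")

    K_like = params.get("K_half")
    if law == "hyperbolic" and K_like is not None and c_max < K_like:
        warnings_out.append(
            f"wide_ci: saturation not approached (max conc {c_max:.3g} < K_half {K_like:.3g})"
        )
    return DoseResponseSeries(
        concentrations=c, k_app=k, law=law, params=params, cov=cov,
        rms=float(np.sqrt(np.mean(resid_abs ** 2))),
        aicc=_aicc(c.size, rss_w, len(free)), warnings=warnings_out,
    )


def select_rate_law(
    concentrations: Sequence[float],
    k_app: Sequence[float],
    candidates: Sequence[str] = ("linear", "hyperbolic"),
    alpha: float = 0.01,
) -> Tuple[str, Dict[str, DoseResponseSeries]]:
    """Fit each candidate law and pick the best-supported one.

    Used for mechanism discrimination: a flexible (induced-fit) effector
    gives a linear concentration dependence of the apparent binding rate; a
    rigid (conformational-selection) effector gives a hyperbolic series
    saturating at the switch rate.

    The linear law is the large-``K_half`` limit of the hyperbolic law, so
    when both are candidates they are compared with an extra-sum-of-squares
    F test at significance ``alpha`` (the hyperbola must earn its extra
    parameter); any remaining comparisons use small-sample AIC.
    """
    fits: Dict[str, DoseResponseSeries] = {}
    for law in candidates:
        try:
            fits[law] = fit_dose_response(concentrations, k_app, law)
        except FitFailureError:
            continue
    if not fits:
        raise FitFailureError("no candidate law could be fitted")
    best = min(fits, key=lambda l: fits[l].aicc)
    if "linear" in fits and "hyperbolic" in fits and best in ("linear", "hyperbolic"):
        from scipy.stats import f as f_dist

        c = np.asarray(concentrations, dtype=float)
        k = np.asarray(k_app, dtype=float)
        W = _dose_weights(k, "relative")
        rss_lin = float(np.sum(((fits["linear"].predict(c) - k) * W) ** 2))
        rss_hyp = float(np.sum(((fits["hyperbolic"].predict(c) - k) * W) ** 2))
        p_lin, p_hyp = 2, 3
        dof = c.size - p_hyp
        if dof > 0 and rss_hyp > 0:
            F = (rss_lin - rss_hyp) / (p_hyp - p_lin) / (rss_hyp / dof)
            p_value = float(f_dist.sf(max(F, 0.0), p_hyp - p_lin, dof))
            best = "hyperbolic" if p_value < alpha else "linear"
    return best, fits


# ---------------------------------------------------------------------------
# equilibrium isotherm
# ---------------------------------------------------------------------------

def fit_isotherm(
    host_concentrations: Sequence[float],
    polarizations: Sequence[float],
    probe_conc: float,
) -> IsothermFitResult:
    """Fit ``P = P0 + P1 f_bound([H]; [E], K_d)`` with the exact quadratic isotherm.

    If the fitted K_d falls below the probe concentration the affinity is
    too strong to be measured and only the upper bound ``K_d < [E]`` is
    reported (``tight_binding`` flag).
    """
    H = np.asarray(host_concentrations, dtype=float)
    P = np.asarray(polarizations, dtype=float)
    if H.shape != P.shape or H.size < 8:
        raise FitFailureError("need >= 8 titration points")
    if probe_conc <= 0:
        raise ValueError("probe_conc must be > 0")
    if np.ptp(P) == 0:
        raise FitFailureError("no binding transition in titration (flat signal)")

    pos = np.sort(H[H > 0])
    kd_seeds = [probe_conc, pos[pos.size // 2], pos[0], pos[-1]] if pos.size else [probe_conc]

    best = None
    objectives = []
    for kd0 in kd_seeds:
        def resid(x):
            f = fraction_bound(H, probe_conc, math.exp(x[0]))
            A = np.column_stack([np.ones_like(f), f])
            coef, *_ = np.linalg.lstsq(A, P, rcond=None)
            return A @ coef - P

        sol = least_squares(resid, [math.log(kd0)], xtol=1e-14, ftol=1e-14, gtol=1e-14)
        obj = float(np.sum(sol.fun ** 2))
        objectives.append(obj)
        if best is None or obj < best[0]:
            best = (obj, float(math.exp(sol.x[0])))
    warnings_out: List[str] = []
    _check_multistart(objectives, warnings_out)
    obj, K_d = best
    f = fraction_bound(H, probe_conc, K_d)
    A = np.column_stack([np.ones_like(f), f])
    coef, *_ = np.linalg.lstsq(A, P, rcond=None)
    resid = A @ coef - P
    rms = float(np.sqrt(np.mean(resid ** 2)))
    P0, P1 = float(coef[0]), float(coef[1])
    if abs(P1) < 2.0 * rms or np.ptp(f) < 1e-3:
        raise FitFailureError("no binding transition in titration", {"P1": P1, "rms": rms})
    tight = K_d < probe_conc
    if tight:
        warnings_out.append(f"tight_binding: fitted K_d {K_d:.3g} M below probe {probe_conc:.3g} M")
    return IsothermFitResult(
        K_d=K_d, P0=P0, P1=P1, probe_conc=probe_conc, tight_binding=tight,
        rms=rms, warnings=warnings_out,
    )


# ---------------------------------------------------------------------------
# reverse facilitated dissociation
# ---------------------------------------------------------------------------

def fit_reverse_fd(
    courses: Sequence[Tuple[float, TimeCourse]],
) -> DoseResponseSeries:
    """Reverse-direction characterization: effector release vs target concentration.

    Each course (labelled effector leaving the host under excess unlabelled
    effector, at one target concentration) is fitted with a single
    exponential decay; the apparent rates are then fitted with
    ``k_app = k_off_TH_E [T] / (K_half + [T]) + k_off_H_E``, whose baseline
    is the unassisted effector off-rate (the zero-target course).
    """
    concs = np.array([c for c, _ in courses], dtype=float)
    if not np.any(concs == 0):
        raise FitFailureError("a zero-target course is required to anchor the base rate")
    pos = concs[concs > 0]
    if pos.size < 3 or pos.max() / pos.min() < 16:
        raise FitFailureError("target series must span at least a 16-fold range")

    kapps = np.array([
        fit_single_exponential(tc, "decay").reported_rate for _, tc in courses
    ])
    series = fit_dose_response(concs, kapps, "hyperbolic")
    # rename to the reverse-direction parameter symbols
    p = series.params
    series.params = {
        "k_off_TH_E": p["k_max"],
        "K_half": p["K_half"],
        "k_off_H_E": p["k_base"],
    }
    return series


# ---------------------------------------------------------------------------
# baseline drift
# ---------------------------------------------------------------------------

def sigmoid_drift(t, S0: float, S1: float, k: float, t_half: float):
    """Logistic baseline drift ``S1 / (1 + e^{-k (t - t_half)}) + S0``."""
    t = np.asarray(t, dtype=float)
    return S1 / (1.0 + np.exp(-k * (t - t_half))) + S0


def fit_sigmoid(tc: TimeCourse) -> Dict[str, float]:
    """Fit the logistic drift model to a reference course (VarPro on S0, S1)."""
    t, y = tc.times, tc.signal.astype(float)
    span = t[-1] - t[0]
    starts = [(4.0 / span, tm) for tm in np.quantile(t, [0.25, 0.5, 0.75])]
    best = None
    for k0, tm0 in starts:
        def resid(x):
            k, tm = math.exp(x[0]), x[1]
            f = 1.0 / (1.0 + np.exp(-k * (t - tm)))
            A = np.column_stack([np.ones_like(f), f])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return A @ coef - y

        sol = least_squares(resid, [math.log(k0), tm0], xtol=1e-14, ftol=1e-14)
        obj = float(np.sum(sol.fun ** 2))
        if best is None or obj < best[0]:
            best = (obj, sol)
    obj, sol = best
    if not sol.success:
        raise FitFailureError("sigmoid fit did not converge")
    k, tm = math.exp(sol.x[0]), float(sol.x[1])
    f = 1.0 / (1.0 + np.exp(-k * (t - tm)))
    A = np.column_stack([np.ones_like(f), f])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return {"S0": float(coef[0]), "S1": float(coef[1]), "k": k, "t_half": tm}


def subtract_sigmoid_drift(tc: TimeCourse, reference_tc: TimeCourse) -> TimeCourse:
    """Fit a logistic drift to a buffer-only reference and subtract it from ``tc``.

    Falls back to constant-baseline subtraction with a warning if the
    sigmoid fit does not converge.  The fitted drift parameters are stored
    in the returned course's metadata.
    """
    if reference_tc.times[0] > tc.times[0] + 1e-9 or reference_tc.times[-1] < tc.times[-1] - 1e-9:
        raise ValueError("reference must cover the time span of the course")
    meta = dict(tc.metadata)
    try:
        if np.ptp(reference_tc.signal) == 0:
            raise FitFailureError("constant reference")
        drift = fit_sigmoid(reference_tc)
        corrected = tc.signal - sigmoid_drift(tc.times, **drift)
        meta["drift_params"] = drift
    except FitFailureError:
        baseline = float(np.mean(reference_tc.signal))
        corrected = tc.signal - baseline
        meta["drift_params"] = {"constant": baseline}
        meta["drift_warning"] = "sigmoid fit non-convergent; constant baseline subtracted"
        logger.warning("sigmoid drift fit failed; subtracting constant baseline")
    return TimeCourse(tc.times, corrected, t0=tc.t0, metadata=meta)
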