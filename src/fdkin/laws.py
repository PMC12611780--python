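"""Closed-form rate laws and equilibrium expressions.

These are the algebraic models fitted to apparent/effective rate constants
and to fluorescence-polarization titrations:

- a linear pseudo-first-order law ``k_app = k_on*[E] + k_off`` (flexible
  effector binding the target-bound host directly),
- the slow relaxation rate of binding by conformational selection (rigid
  effector that can bind only the open state of the switch),
- a hyperbolic saturation law for the effective rate of the full
  facilitated-dissociation process,
- the exact quadratic binding isotherm for the bound fraction at
  comparable probe and titrant concentrations, and the polarization readout.

All functions are numpy-vectorized in their first argument.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kapp_linear",
    "kapp_conformational_selection",
    "kapp_hyperbolic",
    "fraction_bound",
    "polarization",
]


def kapp_linear(E_conc, k_on: float, k_off: float):
    """Apparent rate of one-step binding: ``k_on * [E] + k_off``."""
    E = np.asarray(E_conc, dtype=float)
    out = k_on * E + k_off
    return float(out) if np.isscalar(E_conc) else out


def kapp_conformational_selection(E_conc, k_switch: float, k_unswitch: float,
                                  k_on: float, k_off: float):
    """Slow relaxation rate of binding gated by a conformational pre-equilibrium.

    For the linear three-state scheme ``TH_X <-> TH_Y`` (rates
    ``k_switch``/``k_unswitch``) followed by ``TH_Y + E <-> THE`` under
    pseudo-first-order effector, the observable slow relaxation is

        1/2 (ks + ku + kon[E] + koff)
        - 1/2 sqrt((ks + ku - kon[E] - koff)^2 + 4 ku kon[E]).

    It saturates at ``k_switch`` as [E] grows (the switch becomes
    rate-limiting) and equals the smallest-magnitude nonzero eigenvalue of
    the 3x3 rate matrix.  In the tight-effector regime ``k_off <=
    k_switch`` it is monotone non-decreasing in [E]; with ``k_off``
    above ``k_switch`` the slow relaxation instead decreases towards the
    saturating value.
    """
    E = np.asarray(E_conc, dtype=float)
    a = k_switch + k_unswitch
    b = k_on * E + k_off
    disc = (a - b) ** 2 + 4.0 * k_unswitch * k_on * E
    out = 0.5 * (a + b) - 0.5 * np.sqrt(disc)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(E_conc) else out


def kapp_hyperbolic(conc, k_max: float, K_half: float, k_base: float):
    """Saturating rate law ``k_max * c / (K_half + c) + k_base``.

    ``K_half`` is the concentration giving half the maximal rate increase;
    at ``c = K_half`` the value is ``k_base + k_max / 2``.
    """
    if K_half <= 0:
        raise ValueError("K_half must be > 0")
    c = np.asarray(conc, dtype=float)
    out = k_max * c / (K_half + c) + k_base
    return float(out) if np.isscalar(conc) else out


def fraction_bound(H_tot, E_tot: float, K_d: float):
    """Fraction of probe (effector) bound, exact quadratic isotherm.

    f = ( [H] + [E] + K_d - sqrt(([H]+[E]+K_d)^2 - 4 [H][E]) ) / (2 [E])

    valid without the dilute-probe approximation.  At ``E_tot = 0`` the
    analytic dilute limit ``[H] / ([H] + K_d)`` is returned (documented
    convention rather than NaN).
    """
    if K_d <= 0:
        raise ValueError("K_d must be > 0")
    if E_tot < 0:
        raise ValueError("E_tot must be >= 0")
    H = np.asarray(H_tot, dtype=float)
    if np.any(H < 0):
        raise ValueError("H_tot must be >= 0")
    if E_tot == 0:
        out = H / (H + K_d)
        return float(out) if np.isscalar(H_tot) else out
    s = H + E_tot + K_d
    # sqrt(s^2 - 4 H E) with guard against tiny negative round-off
    disc = np.maximum(s * s - 4.0 * H * E_tot, 0.0)
    out = (s - np.sqrt(disc)) / (2.0 * E_tot)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(H_tot) else out


def polarization(parallel, perpendicular):
    """Fluorescence polarization in mP: ``1000 (I_par - I_perp)/(I_par + I_perp)``."""
    par = np.asarray(parallel, dtype=float)
    perp = np.asarray(perpendicular, dtype=float)
    tot = par + perp
    if np.any(tot <= 0):
        raise ValueError("parallel + perpendicular must be > 0")
    out = 1000.0 * (par - perp) / tot
    return float(out) if np.isscalar(parallel) and np.isscalar(perpendicular) else out
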