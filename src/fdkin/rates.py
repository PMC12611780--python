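"""Rate constants and mechanism topologies for target-host-effector competition.

The systems modelled here consist of a *host* binder H (a conformational
switch fused to a binding module, with closed state X and open state Y), a
*target* T bound by the host, and an *effector* E whose binding to the host
allosterically accelerates target release through a strained ternary complex
THE.  Three competition mechanisms are distinguished:

- ``mutually_exclusive``: E binds only free host; no ternary complex.
- ``conformational_selection``: E binds only the pre-formed open state TH_Y,
  so ternary formation is rate-limited by the TH_X -> TH_Y switch.
- ``induced_fit``: a flexible E engages the closed state TH_X directly and
  drives the transition, bypassing the slow switching step.

All rates are kept internally in seconds and molar; on-rates are
M^-1 s^-1 and off-rates s^-1.  Dissociation constants K_d = k_off / k_on
carry units of M.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, fields
from typing import Optional

SCHEMA_VERSION = 1

#: unit tag for each rate field (on-rates are second order)
_RATE_UNITS = {
    "k_on_TH": "M^-1 s^-1",
    "k_off_TH": "s^-1",
    "k_on_HE": "M^-1 s^-1",
    "k_off_HE": "s^-1",
    "k_on_THE_viaE": "M^-1 s^-1",
    "k_off_THE_toE": "s^-1",
    "k_on_THE_viaT": "M^-1 s^-1",
    "k_off_THE_toT": "s^-1",
    "k_switch": "s^-1",
    "k_unswitch": "s^-1",
    "k_off_THn": "s^-1",
}


class MechanismTopology(str, enum.Enum):
    """The three competition pathways."""

    MUTUALLY_EXCLUSIVE = "mutually_exclusive"
    CONFORMATIONAL_SELECTION = "conformational_selection"
    INDUCED_FIT = "induced_fit"


class ConfigurationError(ValueError):
    """A rate or option required by the requested topology is missing/invalid."""


@dataclass(frozen=True)
class RateConstantSet:
    """Microscopic rate constants of the target/host/effector network.

    Any rate a given topology never uses may be left ``None``.  Rates must
    be non-negative.

    Parameters
    ----------
    k_on_TH, k_off_TH
        Target association to / dissociation from the host (binary TH).
    k_on_HE, k_off_HE
        Effector association to / dissociation from the free host.
    k_on_THE_viaE, k_off_THE_toE
        Effector binding to / release from the target-bound host
        (ternary formation through the effector arm).
    k_on_THE_viaT, k_off_THE_toT
        Target binding to the host-effector complex / accelerated target
        release from the strained ternary complex.
    k_switch, k_unswitch
        TH_X -> TH_Y and TH_Y -> TH_X conformational rates.
    k_off_THn
        Target release from effector-unresponsive host.
    """

    k_on_TH: Optional[float] = None
    k_off_TH: Optional[float] = None
    k_on_HE: Optional[float] = None
    k_off_HE: Optional[float] = None
    k_on_THE_viaE: Optional[float] = None
    k_off_THE_toE: Optional[float] = None
    k_on_THE_viaT: Optional[float] = None
    k_off_THE_toT: Optional[float] = None
    k_switch: Optional[float] = None
    k_unswitch: Optional[float] = None
    k_off_THn: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ConfigurationError(
                    f"rate {f.name} must be finite and >= 0, got {v!r}"
                )

    # -- dissociation constants -------------------------------------------
    def require(self, *names: str) -> None:
        """Raise :class:`ConfigurationError` if any named rate is unset."""
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ConfigurationError(f"missing required rate(s): {', '.join(missing)}")

    @property
    def Kd_TH(self) -> float:
        self.require("k_on_TH", "k_off_TH")
        return self.k_off_TH / self.k_on_TH

    @property
    def Kd_HE(self) -> float:
        self.require("k_on_HE", "k_off_HE")
        return self.k_off_HE / self.k_on_HE

    @property
    def Kd_THE_viaE(self) -> float:
        """Effector affinity for the target-bound host."""
        self.require("k_on_THE_viaE", "k_off_THE_toE")
        return self.k_off_THE_toE / self.k_on_THE_viaE

    @property
    def Kd_THE_viaT(self) -> float:
        """Target affinity for the effector-bound host."""
        self.require("k_on_THE_viaT", "k_off_THE_toT")
        return self.k_off_THE_toT / self.k_on_THE_viaT

    # -- thermodynamic cycle ----------------------------------------------
    def cycle_residual(self) -> float:
        """Log-scale closure error of the T + H + E <-> TH <-> THE <-> HE cycle.

        Zero when the product of association constants along
        T+H -> TH -> THE equals that along H+E -> HE -> THE.
        """
        lhs = (self.k_on_TH / self.k_off_TH) * (self.k_on_THE_viaE / self.k_off_THE_toE)
        rhs = (self.k_on_HE / self.k_off_HE) * (self.k_on_THE_viaT / self.k_off_THE_toT)
        return math.log(lhs / rhs)

    def is_cycle_consistent(self, tol: float = 1e-9) -> bool:
        return abs(self.cycle_residual()) < tol

    @property
    def allosteric_coupling(self) -> float:
        """Mutual destabilization factor alpha.

        Ratio of the target's K_d with saturating effector to its K_d
        without effector; by detailed balance around the closed cycle this
        equals the same ratio for the effector with/without target.
        """
        return self.Kd_THE_viaT / self.Kd_TH

    @classmethod
    def with_closed_cycle(cls, *, solve_for: str = "k_off_THE_toT", **rates: float) -> "RateConstantSet":
        """Build a set whose thermodynamic cycle closes exactly.

        The eight cycle rates minus the one named by ``solve_for`` must be
        supplied; the free rate is computed so the product of equilibrium
        constants around the cycle equals 1.
        """
        cycle = [
            "k_on_TH", "k_off_TH", "k_on_THE_viaE", "k_off_THE_toE",
            "k_on_HE", "k_off_HE", "k_on_THE_viaT", "k_off_THE_toT",
        ]
        if solve_for not in cycle:
            raise ConfigurationError(f"solve_for must be one of the cycle rates, got {solve_for}")
        needed = [n for n in cycle if n != solve_for]
        missing = [n for n in needed if rates.get(n) is None]
        if missing:
            raise ConfigurationError(f"missing required rate(s): {', '.join(missing)}")
        r = dict(rates)
        r.pop(solve_for, None)
        # product of K_assoc around the T-arm over the E-arm must equal 1
        def g(name: str) -> float:
            return r[name]
        if solve_for == "k_off_THE_toT":
            r[solve_for] = (
                g("k_on_THE_viaT") * (g("k_on_HE") / g("k_off_HE"))
                / ((g("k_on_TH") / g("k_off_TH")) * (g("k_on_THE_viaE") / g("k_off_THE_toE")))
            )
        elif solve_for == "k_on_THE_viaT":
            r[solve_for] = (
                g("k_off_THE_toT") * (g("k_on_TH") / g("k_off_TH"))
                * (g("k_on_THE_viaE") / g("k_off_THE_toE"))
                / (g("k_on_HE") / g("k_off_HE"))
            )
        elif solve_for == "k_off_THE_toE":
            r[solve_for] = (
                g("k_on_THE_viaE") * (g("k_on_TH") / g("k_off_TH"))
                / ((g("k_on_HE") / g("k_off_HE")) * (g("k_on_THE_viaT") / g("k_off_THE_toT")))
            )
        elif solve_for == "k_on_THE_viaE":
            r[solve_for] = (
                g("k_off_THE_toE") * (g("k_on_HE") / g("k_off_HE"))
                * (g("k_on_THE_viaT") / g("k_off_THE_toT"))
                / (g("k_on_TH") / g("k_off_TH"))
            )
        else:
            # generic: solve in log space from the closure identity
            raise ConfigurationError(
                f"solving for {solve_for} is not supported; use one of the ternary rates"
            )
        out = cls(**r)
        assert out.is_cycle_consistent(1e-9)
        return out

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return {
            "schema_version": SCHEMA_VERSION,
            "units": {k: _RATE_UNITS[k] for k in d},
            "rates": d,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstantSet":
        if "rates" in d:
            d = d["rates"]
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "RateConstantSet":
        return cls.from_dict(json.loads(s))
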