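"""Mass-action reaction networks for the three competition mechanisms.

A :class:`ReactionNetwork` is a species list plus a list of elementary
reactions (reactant multiset, product multiset, rate constant).  The induced
ODE right-hand side is pure mass action and is integrated with a
stiff-capable solver at tight tolerances, since the rate constants in these
systems span many orders of magnitude.

Species naming: ``T`` (free target), ``H`` (free host), ``E`` (free
effector), ``TH_X``/``TH_Y`` (target-host complex with the switch closed /
open), ``HE`` (host-effector), ``THE`` (strained ternary complex).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .rates import ConfigurationError, MechanismTopology, RateConstantSet

#: element counts (n_T, n_H, n_E) per species, used for conservation checks
SPECIES_COMPOSITION: Dict[str, Tuple[int, int, int]] = {
    "T": (1, 0, 0),
    "H": (0, 1, 0),
    "H_X": (0, 1, 0),
    "H_Y": (0, 1, 0),
    "E": (0, 0, 1),
    "TH_X": (1, 1, 0),
    "TH_Y": (1, 1, 0),
    "HE": (0, 1, 1),
    "THE": (1, 1, 1),
    "THn": (0, 1, 0),
    "T.Hn": (1, 1, 0),
}


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last accepted time."""

    def __init__(self, message: str, t_final: float):
        super().__init__(message)
        self.t_final = t_final


@dataclass(frozen=True)
class Reaction:
    reactants: Tuple[str, ...]
    products: Tuple[str, ...]
    rate: float
    name: str = ""

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{' + '.join(self.reactants) or '0'} -> {' + '.join(self.products) or '0'} (k={self.rate:g})"


@dataclass
class ReactionNetwork:
    """Species and elementary reactions; provides the mass-action RHS."""

    species: List[str]
    reactions: List[Reaction]
    topology: MechanismTopology | None = None
    _index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.species)}
        for rxn in self.reactions:
            for s in rxn.reactants + rxn.products:
                if s not in self._index:
                    raise ConfigurationError(f"reaction references unknown species {s!r}")

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dydt = np.zeros_like(y)
        for rxn in self.reactions:
            flux = rxn.rate
            for s in rxn.reactants:
                flux *= y[self._index[s]]
            for s in rxn.reactants:
                dydt[self._index[s]] -= flux
            for s in rxn.products:
                dydt[self._index[s]] += flux
        return dydt

    def state_vector(self, conc: Mapping[str, float]) -> np.ndarray:
        y = np.zeros(len(self.species))
        for s, c in conc.items():
            if s not in self._index:
                raise ConfigurationError(f"unknown species {s!r} for this topology")
            if c < 0:
                raise ConfigurationError(f"negative initial concentration for {s!r}")
            y[self._index[s]] = c
        return y

    def composition_matrix(self) -> np.ndarray:
        """(n_species, 3) T/H/E composition; unknown species count as empty."""
        return np.array(
            [SPECIES_COMPOSITION.get(s, (0, 0, 0)) for s in self.species], dtype=float
        )

    def totals(self, y: np.ndarray) -> Tuple[float, float, float]:
        """Conserved totals (target, host, effector) of a state vector."""
        t_tot, h_tot, e_tot = self.composition_matrix().T @ np.asarray(y, dtype=float)
        return float(t_tot), float(h_tot), float(e_tot)


def build_network(topology: MechanismTopology, rates: RateConstantSet) -> ReactionNetwork:
    """Assemble the minimal mass-action network for a competition mechanism.

    Reversible binding steps are expanded into forward/back elementary
    reactions.  Missing rates that the topology never uses are permitted;
    a missing required rate raises :class:`ConfigurationError` naming it.
    """
    topology = MechanismTopology(topology)
    rxns: List[Reaction] = []

    def need(*names: str) -> None:
        missing = [n for n in names if getattr(rates, n) is None]
        if missing:
            raise ConfigurationError(
                f"topology {topology.value} requires rate(s): {', '.join(missing)}"
            )

    if topology is MechanismTopology.MUTUALLY_EXCLUSIVE:
        need("k_on_TH", "k_off_TH", "k_on_HE", "k_off_HE")
        species = ["T", "H", "E", "TH_X", "HE"]
        rxns += [
            Reaction(("T", "H"), ("TH_X",), rates.k_on_TH, "T+H->TH_X"),
            Reaction(("TH_X",), ("T", "H"), rates.k_off_TH, "TH_X->T+H"),
            Reaction(("H", "E"), ("HE",), rates.k_on_HE, "H+E->HE"),
            Reaction(("HE",), ("H", "E"), rates.k_off_HE, "HE->H+E"),
        ]
    elif topology is MechanismTopology.CONFORMATIONAL_SELECTION:
        need(
            "k_on_TH", "k_off_TH", "k_switch", "k_unswitch",
            "k_on_THE_viaE", "k_off_THE_toE", "k_off_THE_toT",
            "k_on_HE", "k_off_HE",
        )
        species = ["T", "H", "E", "TH_X", "TH_Y", "THE", "HE"]
        rxns += [
            Reaction(("T", "H"), ("TH_X",), rates.k_on_TH, "T+H->TH_X"),
            Reaction(("TH_X",), ("T", "H"), rates.k_off_TH, "TH_X->T+H"),
            Reaction(("TH_X",), ("TH_Y",), rates.k_switch, "TH_X->TH_Y"),
            Reaction(("TH_Y",), ("TH_X",), rates.k_unswitch, "TH_Y->TH_X"),
            # effector binds only the open, pre-formed state
            Reaction(("TH_Y", "E"), ("THE",), rates.k_on_THE_viaE, "TH_Y+E->THE"),
            Reaction(("THE",), ("TH_Y", "E"), rates.k_off_THE_toE, "THE->TH_Y+E"),
            Reaction(("THE",), ("T", "HE"), rates.k_off_THE_toT, "THE->T+HE"),
            Reaction(("H", "E"), ("HE",), rates.k_on_HE, "H+E->HE"),
            Reaction(("HE",), ("H", "E"), rates.k_off_HE, "HE->H+E"),
        ]
        if rates.k_on_THE_viaT is not None:
            rxns.append(Reaction(("T", "HE"), ("THE",), rates.k_on_THE_viaT, "T+HE->THE"))
    elif topology is MechanismTopology.INDUCED_FIT:
        need(
            "k_on_TH", "k_off_TH", "k_on_THE_viaE", "k_off_THE_toE",
            "k_off_THE_toT", "k_on_HE", "k_off_HE",
        )
        # The transient E.TH_X encounter complex is collapsed into a single
        # committed binding step TH_X + E -> THE carrying k_on_THE_viaE;
        # the flexible effector drives the switch, so no TH_Y intermediate
        # is needed on-pathway.
        species = ["T", "H", "E", "TH_X", "THE", "HE"]
        rxns += [
            Reaction(("T", "H"), ("TH_X",), rates.k_on_TH, "T+H->TH_X"),
            Reaction(("TH_X",), ("T", "H"), rates.k_off_TH, "TH_X->T+H"),
            Reaction(("TH_X", "E"), ("THE",), rates.k_on_THE_viaE, "TH_X+E->THE"),
            Reaction(("THE",), ("TH_X", "E"), rates.k_off_THE_toE, "THE->TH_X+E"),
            Reaction(("THE",), ("T", "HE"), rates.k_off_THE_toT, "THE->T+HE"),
            Reaction(("H", "E"), ("HE",), rates.k_on_HE, "H+E->HE"),
            Reaction(("HE",), ("H", "E"), rates.k_off_HE, "HE->H+E"),
        ]
        if rates.k_on_THE_viaT is not None:
            rxns.append(Reaction(("T", "HE"), ("THE",), rates.k_on_THE_viaT, "T+HE->THE"))
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown topology {topology!r}")

    return ReactionNetwork(species=species, reactions=rxns, topology=topology)


def simulate(
    network: ReactionNetwork,
    initial: Mapping[str, float] | np.ndarray,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float | None = None,
    method: str = "LSODA",
    conservation_tol: float = 1e-6,
) -> Dict[str, np.ndarray]:
    """Integrate the network ODE on an ordered time grid.

    Returns a mapping species -> concentration array (plus ``"t"``).
    ``atol`` defaults to 1e-12 times the largest initial concentration so
    tolerances track the concentration scale of the problem.  Negativity
    beyond integrator tolerance or conserved-total drift above
    ``conservation_tol`` (relative) raises :class:`IntegrationError` rather
    than being clipped.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    y0 = initial if isinstance(initial, np.ndarray) else network.state_vector(initial)
    if np.any(y0 < 0):
        raise ConfigurationError("initial concentrations must be non-negative")
    if atol is None:
        atol = 1e-12 * max(float(np.max(y0)), 1e-300)

    sol = solve_ivp(
        network.rhs, (t[0], t[-1]), y0, t_eval=t, method=method, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", float(sol.t[-1]) if sol.t.size else t[0])

    y = sol.y  # (n_species, n_times)
    scale = max(float(np.max(y0)), atol)
    if np.min(y) < -1e-4 * scale:
        raise IntegrationError(
            f"negative concentration {np.min(y):.3e} beyond tolerance", float(t[-1])
        )
    y = np.where(np.abs(y) < atol, np.maximum(y, 0.0), y)

    # conservation audit on T/H/E totals
    totals = network.composition_matrix().T @ y  # (3, n_times)
    for j, label in enumerate("THE"):
        ref = totals[j, 0]
        if ref > 0:
            drift = np.max(np.abs(totals[j] - ref)) / ref
            if drift > conservation_tol:
                raise IntegrationError(
                    f"total {label} drifted by {drift:.2e} relative", float(t[-1])
                )

    out = {s: y[i] for i, s in enumerate(network.species)}
    out["t"] = t
    return out
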