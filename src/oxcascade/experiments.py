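"""Experimental scenarios: expression ratios, fold inductions and nodule profiles.

Three oxygen environments mirror the wet assays: an atmospheric control
(21% headspace O2), free-living microaerobic culture (1% headspace,
12 uM dissolved) and the in-planta bacteroid environment deep in the
nodule (default 30 nM dissolved, inside the 20-50 nM range reported for
the nitrogen-fixing zone).  Reporter readout is the instantaneous
promoter transcription rate — the quantity a transcriptional fusion
measures — with steady-state protein level available as an option.

When a genotype is multistable at the target O2, the physically selected
state follows the *history rule*: forward integration from that
genotype's free-living steady state, mimicking a bacterium descending
the nodule O2 gradient.  The nodule-zone profile applies the same rule
marching positions from tip (12 uM) to the root-proximal end (30 nM)
along a log-linear prescribed gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
import pandas as pd

from .model import (
    ATMOSPHERIC_FRACTION,
    CascadeState,
    Genotype,
    OxygenCondition,
    ParameterSet,
    promoter_rates,
)
from .steady import scalar_steady_states

__all__ = [
    "Scenario",
    "ZoneProfile",
    "select_state",
    "steady_state_for",
    "expression_ratio",
    "fold_induction",
    "nodule_zone_profile",
]

FREE_LIVING_FRACTION = 0.01
IN_PLANTA_DISSOLVED = 30e-9
IN_PLANTA_ELEVATED_DISSOLVED = 300e-9  # underdeveloped-nodule variant, not used for calibration


class StateRule(str, Enum):
    UNIQUE = "unique"
    HISTORY = "history_from_free_living"


@dataclass(frozen=True)
class Scenario:
    name: str
    oxygen: OxygenCondition
    state_rule: StateRule = StateRule.HISTORY

    @classmethod
    def atmospheric(cls, params: ParameterSet) -> "Scenario":
        return cls(
            "atmospheric",
            OxygenCondition.from_headspace(ATMOSPHERIC_FRACTION, params),
            StateRule.UNIQUE,
        )

    @classmethod
    def free_living_microaerobic(cls, params: ParameterSet) -> "Scenario":
        return cls(
            "free_living_microaerobic",
            OxygenCondition.from_headspace(FREE_LIVING_FRACTION, params),
            StateRule.UNIQUE,
        )

    @classmethod
    def in_planta(
        cls, params: ParameterSet, dissolved: float = IN_PLANTA_DISSOLVED
    ) -> "Scenario":
        if not (10e-9 <= dissolved <= 1e-6):
            raise ValueError("in-planta dissolved O2 outside a plausible nodule range")
        return cls(
            "in_planta",
            OxygenCondition.from_dissolved(dissolved, params),
            StateRule.HISTORY,
        )

    @classmethod
    def from_name(cls, name: str, params: ParameterSet) -> "Scenario":
        factories = {
            "atmospheric": cls.atmospheric,
            "free_living_microaerobic": cls.free_living_microaerobic,
            "free_living": cls.free_living_microaerobic,
            "in_planta": cls.in_planta,
        }
        try:
            return factories[name](params)
        except KeyError:
            raise ValueError(f"unknown scenario {name!r}") from None


@lru_cache(maxsize=16384)
def _select_state_cached(c, params, genotype, rule):
    return _select_state(c, params, genotype, rule, None)


def select_state(
    c: float,
    params: ParameterSet,
    genotype: Genotype,
    rule: StateRule = StateRule.HISTORY,
    history_start: CascadeState | None = None,
) -> CascadeState:
    """Steady state at dissolved O2 ``c``, resolving multistability.

    Monostable systems return their unique state regardless of the rule.
    Under the history rule a multistable system is resolved by forward
    integration from ``history_start`` (default: the genotype's
    free-living microaerobic steady state, itself resolved by
    integration from the atmospheric state).
    """
    if history_start is None:
        return _select_state_cached(c, params, genotype, rule)
    return _select_state(c, params, genotype, rule, history_start)


def _select_state(c, params, genotype, rule, history_start):
    states = scalar_steady_states(c, params, genotype)
    if not states:
        raise RuntimeError(f"no steady state found at c={c:.3g} M")
    if len(states) == 1:
        return states[0]
    if rule is StateRule.UNIQUE:
        raise RuntimeError(
            f"{len(states)} steady states at c={c:.3g} M but the scenario expects a unique one"
        )
    if history_start is None:
        c_free = params.henry_constant * FREE_LIVING_FRACTION
        c_atm = params.henry_constant * ATMOSPHERIC_FRACTION
        atm = select_state(c_atm, params, genotype, StateRule.HISTORY, CascadeState())
        history_start = select_state(c_free, params, genotype, StateRule.HISTORY, atm)
    return _settle_to_root(history_start, c, params, genotype, states)


def _settle_to_root(start, c, params, genotype, states):
    """Integrate just long enough to identify the basin, then snap to the exact root."""
    from scipy.integrate import solve_ivp

    from .model import rhs_vector

    y = start.array
    scale = np.maximum(max(s.array.max() for s in states), 1e-12)
    for _ in range(30):
        sol = solve_ivp(
            lambda _t, yy: rhs_vector(yy, c, params, genotype),
            (0.0, 40.0 / params.delta),
            y,
            method="LSODA",
            rtol=1e-7,
            atol=1e-10 * scale,
        )
        if not sol.success:
            raise RuntimeError(f"history integration failed: {sol.message}")
        y = np.maximum(sol.y[:, -1], 0.0)
        dists = np.array([np.max(np.abs(y - s.array)) for s in states])
        i = int(np.argmin(dists))
        if dists[i] < 1e-4 * scale:
            return states[i]
    # extremely slow passage past a saddle-node ghost: the basin is decided
    # by the FnrN component; snap to the nearest root
    return states[int(np.argmin([abs(y[3] - s.N) for s in states]))]


def steady_state_for(
    genotype: Genotype, scenario: Scenario, params: ParameterSet
) -> CascadeState:
    return select_state(scenario.oxygen.dissolved, params, genotype, scenario.state_rule)


def _readout(
    genotype: Genotype,
    reporter: str,
    scenario: Scenario,
    params: ParameterSet,
    readout: str,
) -> float:
    state = steady_state_for(genotype, scenario, params)
    if readout == "promoter_rate":
        return promoter_rates(state, scenario.oxygen.dissolved, params, genotype)[reporter]
    if readout == "protein":
        if reporter == "fnrN":
            return state.N
        if reporter == "fixNOQP":
            return state.F
        if reporter == "fixK":
            return state.K
        raise ValueError(f"no protein readout for reporter {reporter!r}")
    raise ValueError("readout must be 'promoter_rate' or 'protein'")


def expression_ratio(
    genotype: Genotype,
    reporter: str,
    scenario: Scenario,
    params: ParameterSet,
    readout: str = "promoter_rate",
) -> float:
    """Reporter activity of a mutant relative to wild type, as percent of WT.

    Both strains are evaluated at the scenario's oxygen level; the WT
    average defines 100%, matching the normalisation of the plate-reader
    and bacteroid assays.
    """
    mut = _readout(genotype, reporter, scenario, params, readout)
    wt = _readout(Genotype.wild_type(), reporter, scenario, params, readout)
    if wt <= 0:
        raise RuntimeError("wild-type reporter activity is zero; cannot form a ratio")
    return 100.0 * mut / wt


def fold_induction(
    reporter: str,
    genotype: Genotype,
    high_o2: Scenario,
    low_o2: Scenario,
    params: ParameterSet,
    readout: str = "promoter_rate",
) -> float:
    """Reporter activity at low O2 over high O2 for one strain."""
    hi = _readout(genotype, reporter, high_o2, params, readout)
    lo = _readout(genotype, reporter, low_o2, params, readout)
    if hi <= 0:
        raise RuntimeError("high-O2 reporter activity is zero; fold induction undefined")
    return lo / hi


@dataclass
class ZoneProfile:
    """Reporter expression along the nodule axis (0 = tip, 1 = root-proximal end)."""

    positions: np.ndarray
    dissolved: np.ndarray
    expression: dict  # reporter -> np.ndarray of promoter activities
    genotype: Genotype

    def normalized(self, reporter: str) -> np.ndarray:
        e = self.expression[reporter]
        m = e.max()
        return e / m if m > 0 else e

    def onset_steepness(self, reporter: str) -> tuple[float, float]:
        """Maximum spatial derivative of normalized expression and its position."""
        e = self.normalized(reporter)
        d = np.diff(e) / np.diff(self.positions)
        i = int(np.argmax(d))
        return float(d[i]), float(0.5 * (self.positions[i] + self.positions[i + 1]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for reporter, e in self.expression.items():
            for x, c, v in zip(self.positions, self.dissolved, e):
                rows.append(
                    {"position": x, "dissolved_O2_M": c, "reporter": reporter, "activity": v}
                )
        return pd.DataFrame(rows)


def nodule_zone_profile(
    genotype: Genotype,
    params: ParameterSet,
    n_positions: int = 80,
    o2_tip: float = 12e-6,
    o2_root: float = IN_PLANTA_DISSOLVED,
    reporters: tuple = ("fnrN", "fixNOQP"),
) -> ZoneProfile:
    """Steady-state expression along a prescribed nodule O2 gradient.

    The gradient maps position 0 (tip, zone I) to 1 (root-proximal end of
    the fixing zone) onto a log-linear descent of dissolved O2, 12 uM
    down to 30 nM by default.  The history rule is applied tip to root:
    each position starts from the previous position's state, as a
    bacterium carried down the gradient would.
    """
    if o2_root >= o2_tip:
        raise ValueError("the gradient must descend: o2_root < o2_tip")
    positions = np.linspace(0.0, 1.0, n_positions)
    dissolved = o2_tip * (o2_root / o2_tip) ** positions
    state = select_state(dissolved[0], params, genotype, StateRule.HISTORY)
    expr: dict[str, list] = {r: [] for r in reporters}
    for c in dissolved:
        state = select_state(c, params, genotype, StateRule.HISTORY, history_start=state)
        rates = promoter_rates(state, c, params, genotype)
        for r in reporters:
            expr[r].append(rates[r])
    return ZoneProfile(
        positions, dissolved, {r: np.asarray(v) for r, v in expr.items()}, genotype
    )
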