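"""Core model of the Rlv3841 dual-sensor oxygen regulation cascade.

The cascade couples two oxygen sensors with very different O2 set points.
The membrane kinase hFixL is inactivated by O2 binding with a half point
near 12 uM dissolved O2 (about 1% headspace O2 at equilibrium).  When
active it phosphorylates the response regulator FxkR, which induces the
transcription factor FixK through a K-box operator.  FixK and the second
sensor, FnrN, are FNR-family proteins that bind palindromic anaerobox
operators as dimers and are treated as having identical induction effects
when bound.  FnrN carries an O2-labile iron-sulfur cluster and only
becomes active near 120 nM dissolved O2 (about 0.01% headspace).  The
fnrN promoter carries two anaeroboxes: a distal activating box and a
proximal box whose occupation blocks transcription by steric hindrance,
so FnrN both auto-activates and auto-represses.  The fixNOQP operon
(cbb3-type terminal oxidase) is read out through a single activating
anaerobox.

Five species are modelled: hFixL (L), FxkR (R), FixK (K), FnrN (N) and
FixNOQP (F).  hFixL and FxkR are synthesised constitutively; all species
are removed by a shared first-order rate ``delta`` (dilution/turnover),
set to 1 in the shipped defaults so time is measured in turnover times.
Cooperative steps (hFixL-O2 binding and dimeric DNA binding by FixK and
FnrN) use Hill coefficient 2; FnrN-O2 inactivation is first order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "ParameterSet",
    "CascadeState",
    "Genotype",
    "OxygenCondition",
    "Occupancy",
    "PromoterRates",
    "headspace_to_dissolved",
    "hfixl_active_fraction",
    "fnrn_active_fraction",
    "anaerobox_occupancy",
    "promoter_rates",
    "rhs",
    "rhs_vector",
    "rescale_concentration_units",
]

#: headspace fraction of O2 in air at 1 atm
ATMOSPHERIC_FRACTION = 0.21


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic and affinity constants of the cascade.

    Concentrations of the five species are in arbitrary units (the
    calibration fixes scale only through mutant/WT ratios); dissolved O2
    is in molar.  All parameters must be strictly positive.

    Parameters
    ----------
    henry_constant
        Equilibrium solubility of O2, molar per atmosphere of O2 partial
        pressure.  Fixed at 1.2e-3 M/atm so that 1% headspace O2 maps to
        12 uM dissolved and 0.01% to 120 nM.
    K_L, n_L
        Half-inactivating O2 concentration (molar) and Hill coefficient
        of hFixL; O2 binding is cooperative (n_L = 2).
    K_NO2, n_NO2
        Half-inactivating O2 concentration (molar) and Hill coefficient
        of FnrN cluster oxidation (first order, n_NO2 = 1).
    beta_L, beta_R
        Constitutive synthesis rates of hFixL and FxkR.
    alpha_K, beta_K, K_RK
        Basal and maximal fixK transcription rates and the
        half-saturating active-FxkR level of the K-box.
    alpha_N, beta_N
        Basal and maximal fnrN transcription rates.
    alpha_F, beta_F
        Basal and maximal fixNOQP transcription rates.
    A_K_dist, A_N_dist
        Anaerobox half-saturation constants of FixK and active FnrN at
        the activating distal box of the fnrN promoter.
    rho_K, rho_N
        Multiplicative affinity penalties (> 1) of the proximal
        repressing box of the fnrN promoter, per factor.
    A_K_fix, A_N_fix
        Anaerobox half-saturation constants at the fixNOQP operator
        (distinct sequence context from the fnrN boxes).
    n_DNA
        Hill coefficient of dimeric FixK/FnrN DNA binding (2).
    delta
        Shared first-order removal rate; 1 in the shipped defaults.
    """

    henry_constant: float = 1.2e-3
    K_L: float = 12e-6
    n_L: float = 2.0
    K_NO2: float = 120e-9
    n_NO2: float = 1.0
    beta_L: float = 1.0
    beta_R: float = 1.0
    alpha_K: float = 0.02
    beta_K: float = 1.0
    K_RK: float = 0.25
    alpha_N: float = 0.01
    beta_N: float = 1.0
    alpha_F: float = 0.01
    beta_F: float = 1.0
    A_K_dist: float = 2.0
    A_N_dist: float = 0.5
    rho_K: float = 5.0
    rho_N: float = 3.0
    A_K_fix: float = 4.0
    A_N_fix: float = 0.3
    n_DNA: float = 2.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"parameter {f.name!r} must be finite and > 0, got {v!r}")
        if not self.A_N_dist < self.A_K_dist:
            raise ValueError("A_N_dist must be < A_K_dist (FnrN binds anaeroboxes more tightly than FixK)")
        if not self.A_N_fix < self.A_K_fix:
            raise ValueError("A_N_fix must be < A_K_fix (FnrN binds anaeroboxes more tightly than FixK)")
        if self.rho_K <= 1 or self.rho_N <= 1:
            raise ValueError("rho_K and rho_N are affinity penalties and must be > 1")

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class CascadeState:
    """Concentrations of the five modelled species (arbitrary units)."""

    L: float = 0.0
    R: float = 0.0
    K: float = 0.0
    N: float = 0.0
    F: float = 0.0

    def __post_init__(self) -> None:
        arr = self.array
        if not np.all(np.isfinite(arr)):
            raise ValueError("state components must be finite")
        if np.any(arr < 0):
            raise ValueError("state components must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.L, self.R, self.K, self.N, self.F], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CascadeState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError("expected a length-5 state vector")
        return cls(*map(float, arr))

    def isclose(self, other: "CascadeState", rtol: float = 1e-6, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.array, other.array, rtol=rtol, atol=atol))


SPECIES = ("L", "R", "K", "N", "F")


@dataclass(frozen=True)
class Genotype:
    """Which genes of the cascade are functional.

    A knockout zeroes every synthesis term of the corresponding protein
    (including basal transcription); no other parameter changes.  The
    reporter fusions of the wet assays are plasmid-borne, so promoter
    activities remain defined for knocked-out genes.
    """

    hfixl_functional: bool = True
    fxkr_functional: bool = True
    fixk_functional: bool = True
    fnrn_functional: bool = True

    @classmethod
    def wild_type(cls) -> "Genotype":
        return cls()

    @classmethod
    def delta_hfixl(cls) -> "Genotype":
        """Double hfixL knockout (hfixL9 hfixLc)."""
        return cls(hfixl_functional=False)

    @classmethod
    def delta_fnrn(cls) -> "Genotype":
        return cls(fnrn_functional=False)

    @classmethod
    def delta_both(cls) -> "Genotype":
        return cls(hfixl_functional=False, fnrn_functional=False)

    @classmethod
    def delta_fxkr(cls) -> "Genotype":
        return cls(fxkr_functional=False)

    @property
    def synthesis_mask(self) -> np.ndarray:
        """Per-species indicator of whether any synthesis term exists."""
        return np.array(
            [
                self.hfixl_functional,
                self.fxkr_functional,
                self.fixk_functional,
                self.fnrn_functional,
                True,  # the fixNOQP readout is never knocked out
            ],
            dtype=float,
        )


_GENOTYPE_ALIASES = {
    "wt": Genotype.wild_type,
    "wild_type": Genotype.wild_type,
    "dhfixl": Genotype.delta_hfixl,
    "delta_hfixl": Genotype.delta_hfixl,
    "dfnrn": Genotype.delta_fnrn,
    "delta_fnrn": Genotype.delta_fnrn,
    "dboth": Genotype.delta_both,
    "delta_both": Genotype.delta_both,
    "dfxkr": Genotype.delta_fxkr,
    "delta_fxkr": Genotype.delta_fxkr,
}


def genotype_from_name(name: str) -> Genotype:
    try:
        return _GENOTYPE_ALIASES[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown genotype {name!r}; known: {sorted(_GENOTYPE_ALIASES)}") from None


@dataclass(frozen=True)
class OxygenCondition:
    """An oxygen environment, given as headspace fraction and dissolved molar concentration.

    The two fields are linked through Henry's law at 1 atm total
    pressure: ``dissolved = henry_constant * headspace_fraction``.
    """

    headspace_fraction: float
    dissolved: float

    def __post_init__(self) -> None:
        if self.headspace_fraction < 0 or self.dissolved < 0:
            raise ValueError("oxygen levels must be non-negative")
        if self.headspace_fraction > ATMOSPHERIC_FRACTION * (1 + 1e-9):
            warnings.warn(
                f"headspace fraction {self.headspace_fraction} exceeds the atmospheric "
                f"fraction {ATMOSPHERIC_FRACTION}; not a physically meaningful scenario",
                stacklevel=3,
            )

    @classmethod
    def from_headspace(cls, fraction: float, params: ParameterSet) -> "OxygenCondition":
        return cls(fraction, headspace_to_dissolved(fraction, params))

    @classmethod
    def from_dissolved(cls, dissolved: float, params: ParameterSet) -> "OxygenCondition":
        if dissolved < 0:
            raise ValueError("dissolved O2 must be non-negative")
        return cls(dissolved / params.henry_constant, dissolved)


@dataclass(frozen=True)
class Occupancy:
    """Fractional occupancy of one anaerobox by FixK and active FnrN."""

    theta_fixk: float
    theta_fnrn: float

    @property
    def theta_total(self) -> float:
        return self.theta_fixk + self.theta_fnrn


@dataclass(frozen=True)
class PromoterRates:
    """Instantaneous transcription rates, the readout of a transcriptional fusion."""

    fixK: float
    fnrN: float
    fixNOQP: float

    def __getitem__(self, reporter: str) -> float:
        try:
            return getattr(self, reporter)
        except AttributeError:
            raise KeyError(f"unknown reporter {reporter!r}") from None


def headspace_to_dissolved(fraction: float, params: ParameterSet) -> float:
    """Dissolved O2 (molar) in equilibrium with a headspace O2 fraction at 1 atm.

    Linear in the fraction (Henry's law): 1% headspace gives 12 uM and
    0.01% gives 120 nM with the shipped solubility constant.
    """
    if fraction < 0:
        raise ValueError("headspace fraction must be non-negative")
    return params.henry_constant * fraction


def _check_oxygen(c: float) -> None:
    if not (isinstance(c, (int, float)) and math.isfinite(c)):
        raise ValueError("dissolved O2 must be a finite number")
    if c < 0:
        raise ValueError("dissolved O2 must be non-negative")


def hfixl_active_fraction(c: float, params: ParameterSet) -> float:
    """Fraction of hFixL in the active (kinase) form at dissolved O2 ``c``.

    Repressive Hill function of O2 with cooperativity n_L = 2: fully
    active in anoxia, half active at K_L, inactive at high O2.
    """
    _check_oxygen(c)
    if c == 0:
        return 1.0
    r = (c / params.K_L) ** params.n_L
    return 1.0 / (1.0 + r)


def fnrn_active_fraction(c: float, params: ParameterSet) -> float:
    """Fraction of FnrN with an intact (active) Fe-S cluster at dissolved O2 ``c``."""
    _check_oxygen(c)
    if c == 0:
        return 1.0
    r = (c / params.K_NO2) ** params.n_NO2
    return 1.0 / (1.0 + r)


def anaerobox_occupancy(
    K_conc: float,
    N_active: float,
    A_K: float,
    A_N: float,
    n_DNA: float = 2.0,
) -> Occupancy:
    """Competitive occupancy of one anaerobox by FixK and active FnrN dimers.

    Both factors bind the same operator and cannot co-occupy it; with
    dimeric binding (Hill exponent ``n_DNA``) the occupancies are
    ``x/(1+x+y)`` and ``y/(1+x+y)`` for ``x = (K/A_K)**n`` and
    ``y = (N_active/A_N)**n``.
    """
    if K_conc < 0 or N_active < 0:
        raise ValueError("concentrations must be non-negative")
    if A_K <= 0 or A_N <= 0:
        raise ValueError("affinities must be positive")
    x = (K_conc / A_K) ** n_DNA
    y = (N_active / A_N) ** n_DNA
    z = 1.0 + x + y
    return Occupancy(x / z, y / z)


def _active_fxkr(L: float, R: float, c: float, params: ParameterSet) -> float:
    # Quasi-steady-state phosphorylation: the active pool is the FxkR level
    # times the hFixL O2 transfer function, scaled by sensor abundance
    # relative to its wild-type steady level (beta_L/delta) so that a hfixL
    # knockout silences the branch.
    return R * hfixl_active_fraction(c, params) * (L / (params.beta_L / params.delta))


def promoter_rates(
    state: CascadeState,
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
) -> PromoterRates:
    """Transcription rates of the three regulated promoters at a given state.

    fixK is induced by active FxkR through the K-box with first-order
    saturation.  fnrN is induced through its distal anaerobox and
    sterically repressed through its proximal anaerobox; both FixK and
    active FnrN compete at both boxes, the proximal one with affinities
    penalised by rho_K/rho_N.  fixNOQP is induced through its single
    activating anaerobox.  Knockout effects enter through the state
    (knocked-out proteins decay to zero), not through the rate formulas:
    reporter fusions still read out the promoters of knocked-out genes.
    """
    _check_oxygen(c)
    p = params
    n_act = state.N * fnrn_active_fraction(c, p)
    r_act = _active_fxkr(state.L, state.R, c, p)

    rate_fixk = p.alpha_K + p.beta_K * r_act / (p.K_RK + r_act)

    dist = anaerobox_occupancy(state.K, n_act, p.A_K_dist, p.A_N_dist, p.n_DNA)
    prox = anaerobox_occupancy(
        state.K, n_act, p.A_K_dist * p.rho_K, p.A_N_dist * p.rho_N, p.n_DNA
    )
    rate_fnrn = p.alpha_N + p.beta_N * dist.theta_total * (1.0 - prox.theta_total)

    box_f = anaerobox_occupancy(state.K, n_act, p.A_K_fix, p.A_N_fix, p.n_DNA)
    rate_fixf = p.alpha_F + p.beta_F * box_f.theta_total

    return PromoterRates(rate_fixk, rate_fnrn, rate_fixf)


def rhs_vector(
    y: np.ndarray,
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
) -> np.ndarray:
    """Time derivative of the raw state vector [L, R, K, N, F].

    Array-level variant of :func:`rhs` used by the solvers; does not
    validate non-negativity of the input (Newton iterates may stray
    slightly negative before projection).
    """
    y = np.asarray(y, dtype=float)
    p = params
    state = CascadeState.from_array(np.maximum(y, 0.0))
    rates = promoter_rates(state, c, p, genotype)
    synth = np.array(
        [p.beta_L, p.beta_R, rates.fixK, rates.fnrN, rates.fixNOQP]
    ) * genotype.synthesis_mask
    return synth - p.delta * y


def rhs(
    state: CascadeState,
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
) -> np.ndarray:
    """Time derivative of the cascade state (array ordered L, R, K, N, F).

    Each species balances synthesis against shared first-order removal;
    knocked-out genes have all synthesis zeroed.  Any component at zero
    has a non-negative derivative, so trajectories never go negative.
    """
    return rhs_vector(state.array, c, params, genotype)


def rescale_concentration_units(params: ParameterSet, factor: float) -> ParameterSet:
    """Re-express the parameter set in a concentration unit ``factor`` times smaller.

    Multiplies every synthesis rate and every protein-concentration scale
    (K_RK and the anaerobox affinities) by ``factor``.  Steady-state
    mutant/WT promoter-activity ratios are invariant under this map; the
    oxygen-side constants (K_L, K_NO2, henry_constant) are in molar and
    untouched.
    """
    if factor <= 0:
        raise ValueError("unit rescaling factor must be positive")
    return params.replace(
        beta_L=params.beta_L * factor,
        beta_R=params.beta_R * factor,
        alpha_K=params.alpha_K * factor,
        beta_K=params.beta_K * factor,
        alpha_N=params.alpha_N * factor,
        beta_N=params.beta_N * factor,
        alpha_F=params.alpha_F * factor,
        beta_F=params.beta_F * factor,
        K_RK=params.K_RK * factor,
        A_K_dist=params.A_K_dist * factor,
        A_N_dist=params.A_N_dist * factor,
        A_K_fix=params.A_K_fix * factor,
        A_N_fix=params.A_N_fix * factor,
    )
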