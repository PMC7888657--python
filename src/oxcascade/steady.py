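"""Steady states, stability and bifurcation structure of the cascade.

The cascade has a convenient triangular structure: hFixL, FxkR and (given
those) FixK settle to explicitly computable levels, and only FnrN closes
a feedback loop on itself through its dual-anaerobox promoter.  Every
steady state therefore corresponds to a root of a scalar fixed-point
equation in the FnrN level.  Two independent routes to the steady states
are provided:

* :func:`find_steady_states` — the generic multi-start damped-Newton
  solver on the full five-dimensional right-hand side, seeded from Latin
  hypercube samples (plus optional continuation seeds), as used for the
  oxygen sweeps; and
* :func:`scalar_steady_states` — the exact scalar-reduction route, which
  brackets every root of the FnrN fixed-point equation on a dense grid
  and polishes it with Brent's method.

The two agree to solver tolerance and serve as mutual cross-checks.
Stability is classified from the eigenvalues of a central
finite-difference Jacobian.  A sweep over a descending O2 grid (with
continuation seeding) yields the bifurcation diagram; a contiguous run of
grid points with two stable states, with bisection-refined edges, is the
bistable window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import qmc

from .model import (
    ATMOSPHERIC_FRACTION,
    CascadeState,
    Genotype,
    OxygenCondition,
    ParameterSet,
    fnrn_active_fraction,
    headspace_to_dissolved,
    promoter_rates,
    rhs_vector,
)

__all__ = [
    "Stability",
    "LabelledState",
    "BifurcationBranch",
    "BistableWindow",
    "ConvergenceError",
    "integrate_to_steady",
    "find_steady_states",
    "scalar_steady_states",
    "classify_stability",
    "jacobian",
    "default_oxygen_grid",
    "sweep_bifurcation",
    "detect_bistable_window",
]

#: max-norm tolerance on the right-hand side at a reported root
ROOT_TOL = 1e-9
#: relative distance below which two roots are considered the same
DEDUP_RTOL = 1e-4
#: eigenvalue real-part margin for the stability call
STABILITY_MARGIN = 1e-7


class ConvergenceError(RuntimeError):
    """Raised when time integration fails to reach a steady state."""


class Stability(str, Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"


@dataclass(frozen=True)
class LabelledState:
    state: CascadeState
    oxygen: OxygenCondition
    stability: Stability
    borderline: bool = False  # eigenvalue within the margin of the imaginary axis


@dataclass
class BifurcationBranch:
    """Steady states with stability labels over a descending O2 grid."""

    dissolved_grid: np.ndarray
    points: list  # list (per grid point) of lists of LabelledState
    params: ParameterSet
    genotype: Genotype

    def n_stable(self) -> np.ndarray:
        return np.array(
            [sum(ls.stability is Stability.STABLE for ls in pt) for pt in self.points]
        )

    def stable_expression(self, reporter: str) -> list:
        """Per-grid-point promoter activities of the stable states."""
        out = []
        for c, pt in zip(self.dissolved_grid, self.points):
            vals = [
                promoter_rates(ls.state, c, self.params, self.genotype)[reporter]
                for ls in pt
                if ls.stability is Stability.STABLE
            ]
            out.append(vals)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (c, pt) in enumerate(zip(self.dissolved_grid, self.points)):
            for j, ls in enumerate(pt):
                s = ls.state
                rates = promoter_rates(s, c, self.params, self.genotype)
                rows.append(
                    {
                        "grid_index": i,
                        "root_index": j,
                        "dissolved_O2_M": c,
                        "L": s.L,
                        "R": s.R,
                        "K": s.K,
                        "N": s.N,
                        "F": s.F,
                        "fnrN_activity": rates.fnrN,
                        "fixNOQP_activity": rates.fixNOQP,
                        "stability": ls.stability.value,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BistableWindow:
    """Dissolved-O2 interval over which two stable states coexist."""

    lower: float | None = None
    upper: float | None = None

    @property
    def empty(self) -> bool:
        return self.lower is None

    def contains(self, c: float) -> bool:
        return (not self.empty) and self.lower < c < self.upper


def integrate_to_steady(
    start: CascadeState,
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
    t_max: float = 2000.0,
    tol: float = ROOT_TOL,
) -> CascadeState:
    """Time-march the cascade until the right-hand side max-norm drops below ``tol``.

    Raises
    ------
    ConvergenceError
        If the tolerance is not met within ``t_max`` time units.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    y = start.array
    t = 0.0
    chunk = 50.0
    while t < t_max:
        span = min(chunk, t_max - t)
        sol = solve_ivp(
            lambda _t, yy: rhs_vector(yy, c, params, genotype),
            (0.0, span),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise ConvergenceError(f"integrator failed: {sol.message}")
        y = np.maximum(sol.y[:, -1], 0.0)
        t += span
        if np.max(np.abs(rhs_vector(y, c, params, genotype))) < tol:
            return CascadeState.from_array(y)
    raise ConvergenceError(
        f"no steady state within t_max={t_max} (residual "
        f"{np.max(np.abs(rhs_vector(y, c, params, genotype))):.3g} > tol={tol:.3g})"
    )


def jacobian(
    y: np.ndarray,
    c: float,
    params: ParameterSet,
    genotype: Genotype,
    eps: float = 1e-7,
) -> np.ndarray:
    """Central finite-difference Jacobian of the right-hand side."""
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = eps * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (rhs_vector(yp, c, params, genotype) - rhs_vector(ym, c, params, genotype)) / (
            2 * h
        )
    return J


def _state_scale(params: ParameterSet, genotype: Genotype) -> np.ndarray:
    """Upper bounds on the steady-state components, used for sampling and dedup."""
    p = params
    hi = np.array(
        [
            p.beta_L,
            p.beta_R,
            p.alpha_K + p.beta_K,
            p.alpha_N + p.beta_N,
            p.alpha_F + p.beta_F,
        ]
    ) / p.delta
    return hi * np.where(genotype.synthesis_mask > 0, 1.0, 1e-12) + 1e-12


def _damped_newton(
    y0: np.ndarray,
    c: float,
    params: ParameterSet,
    genotype: Genotype,
    tol: float,
    max_iter: int = 80,
) -> np.ndarray | None:
    y = np.maximum(np.asarray(y0, dtype=float), 0.0)
    f = rhs_vector(y, c, params, genotype)
    for _ in range(max_iter):
        norm = np.max(np.abs(f))
        if norm < tol:
            return y
        J = jacobian(y, c, params, genotype)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(30):
            y_new = np.maximum(y + lam * step, 0.0)
            f_new = rhs_vector(y_new, c, params, genotype)
            if np.max(np.abs(f_new)) < norm:
                break
            lam *= 0.5
        else:
            return None
        y, f = y_new, f_new
    return y if np.max(np.abs(f)) < tol else None


def _dedup(roots: list, scale: np.ndarray) -> list:
    uniq: list[np.ndarray] = []
    for r in roots:
        if not any(np.max(np.abs(r - u) / np.maximum(scale, 1e-30)) < DEDUP_RTOL for u in uniq):
            uniq.append(r)
    uniq.sort(key=lambda r: r[3])  # order by FnrN level
    return uniq


def find_steady_states(
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
    n_starts: int = 50,
    seed: int = 0,
    extra_starts: list | None = None,
    tol: float = ROOT_TOL,
) -> list[CascadeState]:
    """All steady states at dissolved O2 ``c`` by multi-start damped Newton.

    Starts are Latin hypercube samples over the reachable box, plus the
    basal state and any ``extra_starts`` (continuation seeds).  Roots are
    deduplicated by relative distance and returned ordered by FnrN level.
    Deterministic for a fixed seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    scale = _state_scale(params, genotype)
    sampler = qmc.LatinHypercube(d=5, seed=seed)
    starts = [s * scale for s in sampler.random(n_starts)]
    # basal state: all synthesis at its minimal (unregulated) level
    basal = (
        np.array(
            [params.beta_L, params.beta_R, params.alpha_K, params.alpha_N, params.alpha_F]
        )
        * genotype.synthesis_mask
        / params.delta
    )
    starts.append(basal)
    starts.append(scale.copy())
    for s in extra_starts or []:
        starts.append(np.asarray(s, dtype=float))
    roots = []
    for y0 in starts:
        r = _damped_newton(y0, c, params, genotype, tol)
        if r is not None:
            roots.append(r)
    roots = _dedup(roots, scale)
    if not roots:
        warnings.warn(f"no steady state found at c={c:.3g} M", stacklevel=2)
    return [CascadeState.from_array(r) for r in roots]


def _fnrn_fixed_point_map(c, params, genotype):
    """Return (phi, fixed levels): phi(N) = synthesis rate of N at FnrN level N, minus delta*N.

    ``phi`` accepts scalars or arrays (vectorised over N).
    """
    p = params
    g = genotype
    L = p.beta_L / p.delta if g.hfixl_functional else 0.0
    R = p.beta_R / p.delta if g.fxkr_functional else 0.0
    state_lr = CascadeState(L=L, R=R)
    rate_k = promoter_rates(state_lr, c, p, g).fixK
    K = rate_k / p.delta if g.fixk_functional else 0.0

    f_n = fnrn_active_fraction(c, p)
    x_d = (K / p.A_K_dist) ** p.n_DNA
    x_p = (K / (p.A_K_dist * p.rho_K)) ** p.n_DNA

    def phi(N):
        N = np.maximum(N, 0.0)
        if not g.fnrn_functional:
            return -p.delta * N
        n_act = N * f_n
        y_d = (n_act / p.A_N_dist) ** p.n_DNA
        y_p = (n_act / (p.A_N_dist * p.rho_N)) ** p.n_DNA
        t_d = (x_d + y_d) / (1.0 + x_d + y_d)
        t_p = (x_p + y_p) / (1.0 + x_p + y_p)
        return p.alpha_N + p.beta_N * t_d * (1.0 - t_p) - p.delta * N

    return phi, (L, R, K)


def scalar_steady_states(
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
    n_scan: int = 1200,
) -> list[CascadeState]:
    """Exact steady states via the scalar FnrN fixed-point reduction.

    hFixL, FxkR and FixK have no feedback from downstream species, so
    their steady levels are explicit; every steady state corresponds to a
    root of the scalar FnrN balance, located by a dense sign scan and
    Brent refinement.  Returned ordered by FnrN level.
    """
    p = params
    phi, (L, R, K) = _fnrn_fixed_point_map(c, params, genotype)
    if not genotype.fnrn_functional:
        ns = [0.0]
    else:
        n_max = (p.alpha_N + p.beta_N) / p.delta * 1.001
        grid = np.concatenate([[0.0], np.geomspace(n_max * 1e-8, n_max, n_scan)])
        vals = phi(grid)
        ns = []
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if fa == 0.0:
                ns.append(a)
            elif fa * fb < 0:
                ns.append(brentq(phi, a, b, xtol=1e-14, rtol=1e-14))
        if vals[-1] == 0.0:
            ns.append(grid[-1])
        # dedup near-identical roots from grazing sign changes
        uniq = []
        for n in sorted(ns):
            if not uniq or abs(n - uniq[-1]) > DEDUP_RTOL * max(n_max, 1e-30):
                uniq.append(n)
        ns = uniq
    states = []
    for n in ns:
        st = CascadeState(L=L, R=R, K=K, N=n)
        rate_f = promoter_rates(st, c, p, genotype).fixNOQP
        states.append(CascadeState(L=L, R=R, K=K, N=n, F=rate_f / p.delta))
    return states


def classify_stability(
    state: CascadeState,
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
    margin: float = STABILITY_MARGIN,
    steady_tol: float = 1e-6,
) -> Stability:
    """Classify a steady state as stable or unstable from the Jacobian spectrum.

    Stable iff every eigenvalue has real part below ``-margin``.
    Borderline spectra (a real part within the margin) are classified
    unstable and flagged with a warning rather than silently labelled.
    """
    resid = np.max(np.abs(rhs_vector(state.array, c, params, genotype)))
    if resid > steady_tol:
        raise ValueError(f"input is not a steady state (|rhs| = {resid:.3g} > {steady_tol:.3g})")
    eig = np.linalg.eigvals(jacobian(state.array, c, params, genotype))
    re = eig.real
    if np.all(re < -margin):
        return Stability.STABLE
    if np.any(np.abs(re) < margin):
        warnings.warn(
            f"borderline eigenvalue (|Re| < {margin:.1e}) at c={c:.3g}; classifying unstable",
            stacklevel=2,
        )
    return Stability.UNSTABLE


def _label(states, c, params, genotype):
    ox = OxygenCondition.from_dissolved(c, params)
    out = []
    for s in states:
        eig = np.linalg.eigvals(jacobian(s.array, c, params, genotype))
        re = eig.real
        stable = bool(np.all(re < -STABILITY_MARGIN))
        borderline = bool(np.any(np.abs(re) < STABILITY_MARGIN))
        out.append(
            LabelledState(
                s,
                ox,
                Stability.STABLE if stable else Stability.UNSTABLE,
                borderline,
            )
        )
    return out


def default_oxygen_grid(
    params: ParameterSet,
    n_points: int = 200,
    top_fraction: float = ATMOSPHERIC_FRACTION,
    bottom_fraction: float = 1e-5,
) -> np.ndarray:
    """Descending log-spaced dissolved-O2 grid from ~21% to 0.001% headspace."""
    top = headspace_to_dissolved(top_fraction, params)
    bottom = headspace_to_dissolved(bottom_fraction, params)
    return np.geomspace(top, bottom, n_points)


def sweep_bifurcation(
    c_grid: np.ndarray | None = None,
    params: ParameterSet | None = None,
    genotype: Genotype = Genotype.wild_type(),
    seed: int = 0,
    n_starts: int = 50,
) -> BifurcationBranch:
    """Track steady states and their stability over a descending O2 grid.

    Each grid point's Newton starts are augmented with the previous
    point's roots (continuation seeding) so branches are tracked through
    folds without pseudo-arclength machinery.
    """
    if params is None:
        params = ParameterSet()
    if c_grid is None:
        c_grid = default_oxygen_grid(params)
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(np.diff(c_grid) >= 0):
        raise ValueError("c_grid must be strictly descending (high to low O2)")
    points = []
    prev: list[np.ndarray] = []
    for c in c_grid:
        states = find_steady_states(
            c, params, genotype, n_starts=n_starts, seed=seed, extra_starts=prev
        )
        points.append(_label(states, c, params, genotype))
        prev = [s.array for s in states]
    return BifurcationBranch(c_grid, points, params, genotype)


def _n_stable_at(c, params, genotype, seeds, seed=0, n_starts=50):
    states = find_steady_states(c, params, genotype, n_starts=n_starts, seed=seed, extra_starts=seeds)
    labels = _label(states, c, params, genotype)
    return sum(ls.stability is Stability.STABLE for ls in labels), [s.array for s in states]


def detect_bistable_window(
    branch: BifurcationBranch,
    refine_bits: int = 20,
    seed: int = 0,
) -> BistableWindow:
    """Maximal contiguous dissolved-O2 interval with at least two stable states.

    Edges falling between grid points are refined by bisection; an edge
    at the end of the grid is reported at the grid boundary (the window
    may extend beyond the swept range).
    """
    ns = branch.n_stable()
    grid = branch.dissolved_grid
    multi = ns >= 2
    if not multi.any():
        return BistableWindow()
    runs = []
    i = 0
    while i < len(multi):
        if multi[i]:
            j = i
            while j + 1 < len(multi) and multi[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    i, j = max(runs, key=lambda r: r[1] - r[0])

    def bisect_edge(c_multi, c_mono, seeds):
        lo, hi = c_multi, c_mono
        for _ in range(refine_bits):
            mid = float(np.sqrt(lo * hi))
            n, roots = _n_stable_at(mid, branch.params, branch.genotype, seeds, seed=seed)
            if n >= 2:
                lo = mid
                seeds = roots
            else:
                hi = mid
            if abs(hi - lo) <= 1e-12 * max(hi, lo):
                break
        return float(np.sqrt(lo * hi))

    seeds_i = [ls.state.array for ls in branch.points[i]]
    seeds_j = [ls.state.array for ls in branch.points[j]]
    # grid is descending: index i is the high-O2 (upper) edge
    upper = grid[0] if i == 0 else bisect_edge(grid[i], grid[i - 1], seeds_i)
    lower = grid[-1] if j == len(grid) - 1 else bisect_edge(grid[j], grid[j + 1], seeds_j)
    return BistableWindow(lower=float(lower), upper=float(upper))
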