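"""Langevin ensembles: stochastic commitment to the high-expression state.

In the hfixL knockout the FnrN-only circuit is bistable at low O2, with
stable states at near-zero and high fnrN expression.  Expression noise
lets individual cells hop from the low basin to the high one, and the
shallower the low basin becomes as O2 drops, the larger the fraction of
cells that commit — the proposed mechanism for the gradual, patchy onset
of fixNOQP expression in knockout nodules, in contrast to the sharp
all-cells onset of the wild type, whose priming pathway removes the
bistability altogether.

The dynamics are Euler-Maruyama on the deterministic right-hand side
with additive noise of shared amplitude ``sigma`` on every synthesis
term (knocked-out genes have no synthesis term and receive no noise);
negative excursions are reflected at zero.  Molecule counts are not
modelled; the noise amplitude is an illustrative scale, chosen so the
commitment curve of the shipped knockout window spans roughly 5% to 95%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CascadeState, Genotype, ParameterSet
from .steady import (
    STABILITY_MARGIN,
    BistableWindow,
    detect_bistable_window,
    jacobian,
    scalar_steady_states,
)

__all__ = ["EnsembleResult", "simulate_langevin", "commitment_fraction", "DEFAULT_SIGMA"]

#: default noise amplitude on each synthesis term (calibrated so the
#: shipped hfixL-knockout commitment curve spans ~[0.05, 0.95])
DEFAULT_SIGMA = 0.2


def _stable_states(c, params, genotype):
    out = []
    for s in scalar_steady_states(c, params, genotype):
        eig = np.linalg.eigvals(jacobian(s.array, c, params, genotype))
        if np.all(eig.real < -STABILITY_MARGIN):
            out.append(s)
    return out


def simulate_langevin(
    start: CascadeState,
    c: float,
    params: ParameterSet,
    genotype: Genotype = Genotype.wild_type(),
    sigma: float = DEFAULT_SIGMA,
    t_end: float = 50.0,
    dt: float = 1e-3,
    seed: int = 0,
    n_cells: int = 1,
    record_every: int | None = None,
) -> np.ndarray:
    """Euler-Maruyama trajectories of the cascade with synthesis noise.

    Simulates ``n_cells`` independent cells from the same start state.
    Returns an array of shape (n_records, n_cells, 5); with
    ``record_every=None`` only the final state is recorded
    (shape (1, n_cells, 5)).  Deterministic for a fixed seed; ``sigma=0``
    recovers the deterministic flow to integrator accuracy.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    y = np.tile(start.array, (n_cells, 1))
    mask = genotype.synthesis_mask
    sqrt_dt = np.sqrt(dt)
    blow_up = 1e6 * max(1.0, float(np.max(y)))
    records = []
    for step in range(n_steps):
        drift = _rhs_batch(y, c, params, genotype)
        noise = rng.standard_normal(y.shape) * (sigma * sqrt_dt) * mask
        y = np.abs(y + drift * dt + noise)  # reflecting boundary at 0
        if not np.all(np.isfinite(y)) or np.max(y) > blow_up:
            raise RuntimeError(
                f"state norm explosion at t={step * dt:.3g}; the step size dt={dt} "
                "is too large for these parameters"
            )
        if record_every is not None and (step + 1) % record_every == 0:
            records.append(y.copy())
    if record_every is None or not records:
        records = [y.copy()]
    return np.stack(records)


def _rhs_batch(y, c, params, genotype):
    """Vectorised right-hand side over a batch of states, shape (n, 5).

    ``c`` may be a scalar or a per-row array (cells at different oxygen
    levels simulated in one pass).
    """
    p = params
    from .model import fnrn_active_fraction, hfixl_active_fraction

    L, R, K, N, F = (np.maximum(y[:, i], 0.0) for i in range(5))
    if np.isscalar(c):
        f_l = hfixl_active_fraction(c, p)
        f_n = fnrn_active_fraction(c, p)
    else:
        c = np.asarray(c, dtype=float)
        f_l = 1.0 / (1.0 + (c / p.K_L) ** p.n_L)
        f_n = 1.0 / (1.0 + (c / p.K_NO2) ** p.n_NO2)
    r_act = R * f_l * (L / (p.beta_L / p.delta))
    rate_k = p.alpha_K + p.beta_K * r_act / (p.K_RK + r_act)
    n_act = N * f_n
    x_d = (K / p.A_K_dist) ** p.n_DNA
    y_d = (n_act / p.A_N_dist) ** p.n_DNA
    x_p = (K / (p.A_K_dist * p.rho_K)) ** p.n_DNA
    y_p = (n_act / (p.A_N_dist * p.rho_N)) ** p.n_DNA
    t_d = (x_d + y_d) / (1.0 + x_d + y_d)
    t_p = (x_p + y_p) / (1.0 + x_p + y_p)
    rate_n = p.alpha_N + p.beta_N * t_d * (1.0 - t_p)
    x_f = (K / p.A_K_fix) ** p.n_DNA
    y_f = (n_act / p.A_N_fix) ** p.n_DNA
    rate_f = p.alpha_F + p.beta_F * (x_f + y_f) / (1.0 + x_f + y_f)
    synth = np.stack(
        [np.full_like(L, p.beta_L), np.full_like(L, p.beta_R), rate_k, rate_n, rate_f], axis=1
    )
    return synth * genotype.synthesis_mask - p.delta * y


def _simulate_batch(y0, c, params, genotype, sigma, t_end, dt, rng):
    n_steps = int(round(t_end / dt))
    y = y0.copy()
    mask = genotype.synthesis_mask
    sqrt_dt = np.sqrt(dt)
    for _ in range(n_steps):
        drift = _rhs_batch(y, c, params, genotype)
        y = np.abs(y + drift * dt + rng.standard_normal(y.shape) * (sigma * sqrt_dt) * mask)
    if not np.all(np.isfinite(y)):
        raise RuntimeError(f"state norm explosion; reduce dt={dt}")
    return y


@dataclass
class EnsembleResult:
    """Commitment fractions of a cell population over an O2 grid."""

    dissolved_grid: np.ndarray
    fraction_high: np.ndarray  # NaN where no high branch is defined
    n_stable: np.ndarray
    n_cells: int
    sigma: float
    seed: int
    window: BistableWindow

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dissolved_O2_M": self.dissolved_grid,
                "fraction_high": self.fraction_high,
                "n_stable": self.n_stable,
                "n_cells": self.n_cells,
                "sigma": self.sigma,
                "seed": self.seed,
            }
        )


def commitment_fraction(
    c_grid: np.ndarray,
    params: ParameterSet,
    genotype: Genotype = Genotype.delta_hfixl(),
    sigma: float = DEFAULT_SIGMA,
    n_cells: int = 500,
    t_end: float = 50.0,
    dt: float = 1e-3,
    seed: int = 0,
) -> EnsembleResult:
    """Fraction of cells committed to the high-expression basin at each O2.

    At each grid point all cells start at the low/basal stable state and
    evolve for ``t_end`` turnover times; a cell is committed if its final
    state is nearest (relative distance) to the high-FnrN stable state.
    Points above the bistable window have no high branch and report 0;
    points below its lower edge have lost the low branch and report 1;
    the Langevin ensemble is simulated only where both basins exist.
    For a genotype with no bistable window anywhere (the wild type) the
    fraction is NaN at every point — commitment is degenerate because
    there is only ever a single basin.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(np.diff(c_grid) >= 0):
        raise ValueError("c_grid must be strictly descending")
    from .steady import sweep_bifurcation

    branch = sweep_bifurcation(c_grid, params, genotype, seed=seed, n_starts=20)
    window = detect_bistable_window(branch, seed=seed)
    n_stable = branch.n_stable()
    rng = np.random.default_rng(seed)
    fractions = np.full(c_grid.size, np.nan)
    sim_points = []  # (grid index, stable states) with both basins present
    for i, c in enumerate(c_grid):
        if window.empty:
            continue
        stables = _stable_states(c, params, genotype)
        if len(stables) < 2:
            fractions[i] = 0.0 if c >= window.upper else 1.0
            continue
        sim_points.append((i, stables))
    if sim_points:
        # one Euler-Maruyama pass over every simulated point's cells
        y0 = np.concatenate(
            [np.tile(st[0].array, (n_cells, 1)) for _, st in sim_points]
        )
        c_vec = np.repeat([c_grid[i] for i, _ in sim_points], n_cells)
        y_end = _simulate_batch(y0, c_vec, params, genotype, sigma, t_end, dt, rng)
        for k, (i, stables) in enumerate(sim_points):
            block = y_end[k * n_cells : (k + 1) * n_cells]
            scale = np.maximum(stables[-1].array, 1e-9)
            targets = np.stack([s.array for s in stables])
            d = np.linalg.norm((block[:, None, :] - targets[None, :, :]) / scale, axis=2)
            nearest = np.argmin(d, axis=1)
            fractions[i] = float(np.mean(nearest == len(stables) - 1))
    return EnsembleResult(
        c_grid, fractions, n_stable, n_cells, sigma, seed, window
    )
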