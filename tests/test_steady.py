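"""Steady-state solvers, stability classification and the bistable window.

The damped-Newton multi-start solver is checked against two independent
oracles: the exact scalar FnrN fixed-point reduction and long-time
integration (for stable states, perturb-and-integrate must return).
"""

import numpy as np
import pytest

from oxcascade.model import CascadeState, Genotype, ParameterSet, headspace_to_dissolved, rhs_vector
from oxcascade.steady import (
    ConvergenceError,
    Stability,
    classify_stability,
    default_oxygen_grid,
    detect_bistable_window,
    find_steady_states,
    integrate_to_steady,
    scalar_steady_states,
    sweep_bifurcation,
)

GENOTYPES = [
    Genotype.wild_type(),
    Genotype.delta_hfixl(),
    Genotype.delta_fnrn(),
    Genotype.delta_both(),
    Genotype.delta_fxkr(),
]


class TestIntegrateToSteady:
    def test_atmospheric_wild_type_settles_near_basal(self, defaults):
        c = headspace_to_dissolved(0.21, defaults)
        st = integrate_to_steady(CascadeState(), c, defaults)
        assert np.max(np.abs(rhs_vector(st.array, c, defaults, Genotype.wild_type()))) < 1e-9
        # sensors are off: fixK transcription is close to basal
        assert st.K < (defaults.alpha_K + 0.15 * defaults.beta_K) / defaults.delta

    def test_fnrn_knockout_protein_decays_to_zero(self, defaults, dfnrn):
        st = integrate_to_steady(CascadeState(N=1.0), 1e-7, defaults, dfnrn)
        assert st.N < 1e-10

    def test_non_convergence_is_an_explicit_error(self, defaults):
        with pytest.raises(ConvergenceError):
            integrate_to_steady(CascadeState(), 12e-6, defaults, t_max=1e-3)


class TestRootFinding:
    @pytest.mark.parametrize("genotype", GENOTYPES, ids=lambda g: str(g.synthesis_mask))
    @pytest.mark.parametrize("c", [252e-6, 12e-6, 120e-9, 30e-9, 1.2e-9])
    def test_newton_agrees_with_scalar_reduction(self, defaults, genotype, c):
        newton = find_steady_states(c, defaults, genotype, n_starts=40, seed=0)
        scalar = scalar_steady_states(c, defaults, genotype)
        assert len(newton) == len(scalar)
        for a, b in zip(newton, scalar):
            np.testing.assert_allclose(a.array, b.array, rtol=1e-6, atol=1e-10)

    def test_every_root_satisfies_the_tolerance(self, defaults, dhfixl):
        for st in find_steady_states(60e-9, defaults, dhfixl, seed=1):
            assert np.max(np.abs(rhs_vector(st.array, 60e-9, defaults, dhfixl))) < 1e-9

    def test_duplicate_starts_do_not_duplicate_roots(self, defaults):
        base = find_steady_states(12e-6, defaults, seed=0)
        seeded = find_steady_states(
            12e-6, defaults, seed=0, extra_starts=[base[0].array] * 5
        )
        assert len(seeded) == len(base)

    def test_deterministic_for_fixed_seed(self, defaults, dhfixl):
        a = find_steady_states(60e-9, defaults, dhfixl, seed=42)
        b = find_steady_states(60e-9, defaults, dhfixl, seed=42)
        assert all(x.array.tolist() == y.array.tolist() for x, y in zip(a, b))


class TestStability:
    def test_basal_state_at_atmospheric_oxygen_is_stable(self, defaults):
        c = headspace_to_dissolved(0.21, defaults)
        (st,) = find_steady_states(c, defaults, seed=0)
        assert classify_stability(st, c, defaults) is Stability.STABLE
        # perturb-and-integrate oracle returns to the same state
        pert = CascadeState.from_array(st.array * 1.05 + 1e-6)
        back = integrate_to_steady(pert, c, defaults)
        np.testing.assert_allclose(back.array, st.array, rtol=1e-6, atol=1e-9)

    def test_middle_state_of_three_is_unstable(self, defaults, dhfixl):
        c = self._bistable_point(defaults)
        states = find_steady_states(c, defaults, dhfixl, seed=0)
        assert len(states) == 3
        assert classify_stability(states[1], c, defaults, dhfixl) is Stability.UNSTABLE
        # perturbing off the middle state diverges to one of the outer states
        eps = 1e-3 * max(states[1].N, 1e-6)
        up = integrate_to_steady(
            CascadeState.from_array(states[1].array + [0, 0, 0, eps, 0]), c, defaults, dhfixl
        )
        down = integrate_to_steady(
            CascadeState.from_array(np.maximum(states[1].array - [0, 0, 0, eps, 0], 0)),
            c, defaults, dhfixl,
        )
        assert up.N == pytest.approx(states[2].N, rel=1e-5)
        assert down.N == pytest.approx(states[0].N, rel=1e-5)

    def test_non_steady_input_is_an_error(self, defaults):
        with pytest.raises(ValueError):
            classify_stability(CascadeState(N=0.123), 12e-6, defaults)

    @staticmethod
    def _bistable_point(params):
        grid = default_oxygen_grid(params, n_points=80)
        for c in grid:
            if len(scalar_steady_states(c, params, Genotype.delta_hfixl())) == 3:
                return c
        pytest.fail("no bistable point found for the hfixL knockout")


class TestSweepAndWindow:
    def test_wild_type_sweep_is_monostable_with_stable_labels(self, defaults):
        grid = default_oxygen_grid(defaults, n_points=40)
        branch = sweep_bifurcation(grid, defaults, seed=0, n_starts=25)
        assert (branch.n_stable() == 1).all()
        assert detect_bistable_window(branch).empty

    def test_knockout_window_is_below_the_fnrn_threshold(self, defaults, dhfixl):
        grid = default_oxygen_grid(defaults, n_points=60)
        branch = sweep_bifurcation(grid, defaults, dhfixl, seed=0, n_starts=25)
        window = detect_bistable_window(branch, seed=0)
        assert not window.empty
        assert window.upper <= 120e-9
        assert window.lower < window.upper
        # every interior grid point carries two stable states
        inside = (grid < window.upper) & (grid > window.lower)
        assert (branch.n_stable()[inside] >= 2).all()

    def test_stability_labels_agree_with_perturb_and_integrate(self, defaults, dhfixl):
        grid = default_oxygen_grid(defaults, n_points=12)
        branch = sweep_bifurcation(grid, defaults, dhfixl, seed=0, n_starts=20)
        rng = np.random.default_rng(0)
        for c, pt in zip(grid, branch.points):
            for ls in pt:
                if ls.stability is not Stability.STABLE:
                    continue
                pert = ls.state.array * (1 + 0.02 * rng.standard_normal(5))
                back = integrate_to_steady(
                    CascadeState.from_array(np.maximum(pert, 0)), c, defaults, dhfixl
                )
                np.testing.assert_allclose(
                    back.array, ls.state.array, rtol=1e-5, atol=1e-9
                )

    def test_window_bounds_stable_under_grid_refinement(self, defaults, dhfixl):
        coarse_grid = np.geomspace(150e-9, 2e-9, 30)
        fine_grid = np.geomspace(150e-9, 2e-9, 60)
        w_coarse = detect_bistable_window(
            sweep_bifurcation(coarse_grid, defaults, dhfixl, seed=0, n_starts=20), seed=0
        )
        w_fine = detect_bistable_window(
            sweep_bifurcation(fine_grid, defaults, dhfixl, seed=0, n_starts=20), seed=0
        )
        assert not w_coarse.empty and not w_fine.empty
        # bisection-refined edges agree to better than one coarse cell
        cell = np.log(coarse_grid[0] / coarse_grid[1])
        for a, b in [(w_coarse.upper, w_fine.upper), (w_coarse.lower, w_fine.lower)]:
            if a in coarse_grid or b in fine_grid:  # edge at a grid end: unrefined
                continue
            assert abs(np.log(a / b)) < cell

    def test_branch_export_is_tidy(self, defaults):
        grid = default_oxygen_grid(defaults, n_points=5)
        frame = sweep_bifurcation(grid, defaults, seed=0, n_starts=10).to_frame()
        assert {"dissolved_O2_M", "N", "stability", "fnrN_activity"} <= set(frame.columns)
        assert len(frame) >= 5
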