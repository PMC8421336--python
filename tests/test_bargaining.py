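"""Best responses, fixed-theta agreements, threat points, bargain selection.

The independent oracles here deliberately avoid the solver's code path:
they score candidates with the scalar reference utility
(:func:`hhbargain.utility_member`) over fine or exhaustive grids.
"""

from __future__ import annotations

import numpy as np
import pytest

from hhbargain import (
    Bargain,
    Direction,
    Gender,
    Household,
    NormState,
    Role,
    SolverSettings,
    best_response,
    brute_force_bargain,
    equilibrium_at_theta,
    select_bargain,
    threat_point,
    utility_member,
)
from hhbargain.bargaining import nash_product

from conftest import make_agent, make_household, random_household

COARSE = SolverSettings(alpha_grid_step=0.05, theta_grid_step=0.1)


def fine_grid_best_alpha(role, partner_alpha, theta_signed, params_A,
                         params_B, norm, step=1e-4):
    """Oracle: scan alpha at high resolution with the reference utility.

    ``params_A``/``params_B`` are always in household order; ``role`` names
    the member whose time is being optimized.
    """
    best_a, best_u = 0.0, -1.0
    for a in np.arange(0.0, 1.0 + step / 2, step):
        if role is Role.A:
            b = Bargain.from_signed(float(a), partner_alpha, theta_signed)
        else:
            b = Bargain.from_signed(partner_alpha, float(a), theta_signed)
        u = utility_member(role, b, params_A, params_B, norm)
        if u > best_u:
            best_a, best_u = float(a), u
    return best_a


class TestBestResponse:
    def test_pure_public_preference_corner(self):
        params = make_agent("f0", Gender.FEMALE, p_alpha=0.0, wage=0.6)
        partner = make_agent("m0", Gender.MALE, p_alpha=0.5, wage=0.6)
        alloc = best_response(Role.A, 0.5, 0.0, params, partner, None,
                              SolverSettings())
        assert alloc.alpha == 0.0

    @pytest.mark.parametrize("theta_signed", [0.0, 0.3, -0.3])
    def test_matches_fine_grid_oracle(self, theta_signed):
        params = make_agent("f0", Gender.FEMALE, p_alpha=0.5, wage=0.6)
        partner = make_agent("m0", Gender.MALE, p_alpha=0.5, wage=0.6)
        settings = SolverSettings()
        alloc = best_response(Role.A, 0.5, theta_signed, params, partner,
                              None, settings)
        oracle = fine_grid_best_alpha(Role.A, 0.5, theta_signed, params,
                                      partner, None)
        assert abs(alloc.alpha - oracle) <= settings.alpha_grid_step

    def test_huge_conformity_pins_behavior_to_the_norm(self):
        norm = NormState("female", {"alpha": 0.2, "gamma": 0.8, "theta": 0.0})
        params = make_agent("f0", Gender.FEMALE, p_alpha=0.5,
                            conformity=1e4, wage=0.6)
        partner = make_agent("m0", Gender.MALE, p_alpha=0.5, wage=0.6)
        settings = SolverSettings()
        alloc = best_response(Role.A, 0.5, 0.0, params, partner,
                              {Gender.FEMALE: norm}[Gender.FEMALE], settings)
        assert abs(alloc.alpha - 0.2) <= settings.alpha_grid_step


class TestEquilibrium:
    def test_fixed_point_is_stable(self, zero_conf_household):
        s = SolverSettings()
        bargain, converged = equilibrium_at_theta(
            zero_conf_household, 0.0, {}, s)
        assert converged
        hh2 = Household(zero_conf_household.params_A,
                        zero_conf_household.params_B, prev_bargain=bargain)
        again, _ = equilibrium_at_theta(hh2, 0.0, {}, s)
        assert again.alloc_A.alpha == bargain.alloc_A.alpha
        assert again.alloc_B.alpha == bargain.alloc_B.alpha

    def test_symmetric_agents_reach_symmetric_agreement(self):
        # A moves first in the alternation, so on a grid the members may
        # settle one cell apart; symmetry holds to grid resolution
        hh = make_household(p_alpha_A=0.5, p_alpha_B=0.5, w_A=0.6, w_B=0.6)
        s = SolverSettings()
        bargain, _ = equilibrium_at_theta(hh, 0.0, {}, s)
        assert abs(bargain.alloc_A.alpha - bargain.alloc_B.alpha) \
            <= s.alpha_grid_step + 1e-9

    def test_agreement_is_joint_grid_nash_equilibrium(self):
        """Oracle: the agreement must appear among the grid's mutual best
        responses, found by exhaustive scoring with the reference utility."""
        hh = make_household(p_alpha_A=0.5, p_alpha_B=0.5, w_A=0.6, w_B=0.6)
        s = SolverSettings(alpha_grid_step=0.05)
        grid = s.alpha_grid()
        u_A = np.array([[utility_member(
            Role.A, Bargain.from_signed(a, b, 0.0), hh.params_A, hh.params_B,
            None) for b in grid] for a in grid])
        u_B = np.array([[utility_member(
            Role.B, Bargain.from_signed(a, b, 0.0), hh.params_A, hh.params_B,
            None) for b in grid] for a in grid])
        nash_cells = {
            (round(float(grid[i]), 10), round(float(grid[j]), 10))
            for i in range(grid.size) for j in range(grid.size)
            if u_A[i, j] >= u_A[:, j].max() - 1e-12
            and u_B[i, j] >= u_B[i, :].max() - 1e-12
        }
        bargain, _ = equilibrium_at_theta(hh, 0.0, {}, s)
        assert (round(bargain.alloc_A.alpha, 10),
                round(bargain.alloc_B.alpha, 10)) in nash_cells


class TestThreatPoint:
    def test_equals_utilities_at_zero_transfer_agreement(self):
        hh = make_household(p_alpha_A=0.4, p_alpha_B=0.6)
        s = SolverSettings()
        tp = threat_point(hh, {}, s)
        bargain, _ = equilibrium_at_theta(hh, 0.0, {}, s)
        assert tp.utility_A == pytest.approx(
            utility_member(Role.A, bargain, hh.params_A, hh.params_B, None))
        assert tp.utility_B == pytest.approx(
            utility_member(Role.B, bargain, hh.params_A, hh.params_B, None))

    def test_symmetric_household_equal_threats(self):
        # equal up to the one-cell asymmetry of the A-first alternation
        hh = make_household(p_alpha_A=0.5, p_alpha_B=0.5, w_A=0.6, w_B=0.6)
        tp = threat_point(hh, {}, SolverSettings())
        assert tp.utility_A == pytest.approx(tp.utility_B, abs=0.01)

    def test_fixture_household_matches_fine_grid_recomputation(self):
        hh = make_household(p_alpha_A=0.4, p_alpha_B=0.6, w_A=0.1, w_B=0.6)
        tp = threat_point(hh, {}, SolverSettings())
        # independent alternation on a 1e-4 grid
        a_A, a_B = 0.0, 0.0
        for _ in range(200):
            new_A = fine_grid_best_alpha(Role.A, a_B, 0.0, hh.params_A,
                                         hh.params_B, None, step=1e-3)
            new_B = fine_grid_best_alpha(Role.B, new_A, 0.0, hh.params_A,
                                         hh.params_B, None, step=1e-3)
            if abs(new_A - a_A) < 1e-9 and abs(new_B - a_B) < 1e-9:
                break
            a_A, a_B = new_A, new_B
        b = Bargain.from_signed(a_A, a_B, 0.0)
        assert tp.utility_A == pytest.approx(
            utility_member(Role.A, b, hh.params_A, hh.params_B, None), abs=1e-3)
        assert tp.utility_B == pytest.approx(
            utility_member(Role.B, b, hh.params_A, hh.params_B, None), abs=1e-3)


class TestSelectBargain:
    def test_no_pareto_improving_transfer_returns_separate_spheres(self):
        # identical members: any transfer hurts the transferor
        hh = make_household(p_alpha_A=0.5, p_alpha_B=0.5, w_A=0.6, w_B=0.6)
        bargain = select_bargain(hh, {}, SolverSettings())
        assert bargain.theta == 0.0
        assert bargain.direction is Direction.NONE

    def test_higher_earner_transfers_and_brute_force_agrees(self):
        hh = make_household(p_alpha_A=0.5, p_alpha_B=0.5, w_A=0.1, w_B=0.6)
        sel = select_bargain(hh, {}, COARSE)
        assert sel.direction is Direction.B_TO_A
        bf = brute_force_bargain(hh, {}, COARSE)
        assert bf.direction is Direction.B_TO_A
        tp = threat_point(hh, {}, COARSE)
        p_sel = nash_product(sel, hh, {}, tp)
        p_bf = nash_product(bf, hh, {}, tp)
        # brute force roams the whole joint grid, so it may edge out the
        # two-step agreement by at most a cell's worth of objective
        assert p_sel == pytest.approx(p_bf, abs=0.02)
        assert sel.theta == pytest.approx(bf.theta, abs=COARSE.theta_grid_step)

    def test_nash_product_is_exhaustive_maximum_over_agreements(self):
        hh = make_household(p_alpha_A=0.4, p_alpha_B=0.6, w_A=0.2, w_B=0.8)
        s = COARSE
        sel = select_bargain(hh, {}, s)
        tp = threat_point(hh, {}, s)
        best = nash_product(sel, hh, {}, tp)
        for th in s.theta_signed_grid():
            bargain, _ = equilibrium_at_theta(hh, float(th), {}, s)
            u_A = utility_member(Role.A, bargain, hh.params_A, hh.params_B, None)
            u_B = utility_member(Role.B, bargain, hh.params_A, hh.params_B, None)
            if u_A < tp.utility_A - s.constraint_tol:
                continue
            if u_B < tp.utility_B - s.constraint_tol:
                continue
            assert best >= nash_product(bargain, hh, {}, tp) - 1e-9

    def test_participation_constraints_hold(self):
        rng = np.random.default_rng(11)
        s = COARSE
        for _ in range(10):
            hh = random_household(rng)
            norms = {
                Gender.FEMALE: NormState(
                    "female", {"alpha": 0.2, "gamma": 0.8, "theta": 0.0}),
                Gender.MALE: NormState(
                    "male", {"alpha": 0.8, "gamma": 0.2, "theta": 0.0}),
            }
            sel = select_bargain(hh, norms, s)
            tp = threat_point(hh, norms, s)
            u_A = utility_member(Role.A, sel, hh.params_A, hh.params_B,
                                 norms[Gender.FEMALE])
            u_B = utility_member(Role.B, sel, hh.params_A, hh.params_B,
                                 norms[Gender.MALE])
            assert u_A >= tp.utility_A - s.constraint_tol
            assert u_B >= tp.utility_B - s.constraint_tol
            assert sel.alloc_A.alpha + sel.alloc_A.gamma == pytest.approx(1.0)
            assert sel.alloc_B.alpha + sel.alloc_B.gamma == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        # the first mover changes with the labels, so allocations mirror to
        # grid resolution; transfer magnitude and direction must mirror
        hh = make_household(p_alpha_A=0.4, p_alpha_B=0.6, w_A=0.2, w_B=0.9)
        swapped = Household(params_A=hh.params_B, params_B=hh.params_A)
        s = COARSE
        b1 = select_bargain(hh, {}, s)
        b2 = select_bargain(swapped, {}, s)
        assert b1.alloc_A.alpha == pytest.approx(b2.alloc_B.alpha,
                                                 abs=s.alpha_grid_step)
        assert b1.alloc_B.alpha == pytest.approx(b2.alloc_A.alpha,
                                                 abs=s.alpha_grid_step)
        assert b1.theta == pytest.approx(b2.theta, abs=s.theta_grid_step)
        assert b1.theta_signed == pytest.approx(-b2.theta_signed,
                                                abs=s.theta_grid_step) \
            or b1.theta == 0.0

    def test_determinism(self):
        hh = make_household(p_alpha_A=0.37, p_alpha_B=0.63, w_A=0.3, w_B=0.7)
        s = SolverSettings()
        b1 = select_bargain(hh, {}, s)
        b2 = select_bargain(hh, {}, s)
        assert b1 == b2

    def test_raising_a_wage_never_lowers_summed_goods_utility(self):
        s = COARSE
        utils = []
        for w_B in (0.4, 0.6, 0.8):
            hh = make_household(p_alpha_A=0.45, p_alpha_B=0.55,
                                w_A=0.3, w_B=w_B)
            sel = select_bargain(hh, {}, s)
            u = (utility_member(Role.A, sel, hh.params_A, hh.params_B, None)
                 + utility_member(Role.B, sel, hh.params_A, hh.params_B, None))
            utils.append(u)
        assert all(b >= a - 1e-9 for a, b in zip(utils, utils[1:]))


class TestBruteForce:
    def test_fine_grids_refused(self):
        hh = make_household()
        with pytest.raises(ValueError):
            brute_force_bargain(hh, {}, SolverSettings())

    def test_theta_grid_zero_only_degenerates_to_separate_spheres(self):
        hh = make_household(w_A=0.1, w_B=0.6)
        s = SolverSettings(alpha_grid_step=0.05, theta_grid_step=1.0)
        bf = brute_force_bargain(hh, {}, s)
        eq, _ = equilibrium_at_theta(hh, 0.0, {}, s)
        # theta=1 is the only non-zero candidate; if infeasible the
        # separate-spheres agreement must come back unchanged
        if bf.theta == 0.0:
            assert bf.alloc_A.alpha == eq.alloc_A.alpha
            assert bf.alloc_B.alpha == eq.alloc_B.alpha

    def test_symmetric_household_optimum_set_is_mirror_invariant(self):
        # the brute-force argmax of a symmetric household need not be
        # symmetric itself (coordination-gain bargains come in mirror
        # pairs); its mirror must score identically
        hh = make_household(p_alpha_A=0.5, p_alpha_B=0.5, w_A=0.6, w_B=0.6)
        bf = brute_force_bargain(hh, {}, COARSE)
        tp = threat_point(hh, {}, COARSE)
        mirrored = Bargain.from_signed(bf.alloc_B.alpha, bf.alloc_A.alpha,
                                       -bf.theta_signed)
        assert nash_product(bf, hh, {}, tp) == pytest.approx(
            nash_product(mirrored, hh, {}, tp), abs=1e-9)
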