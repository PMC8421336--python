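"""The intra-household bargain.

Bargains are found in two steps, following the separate-spheres Nash
bargaining tradition:

1. For each candidate transfer level theta (in both directions), the two
   members alternate best responses over their own time allocation until the
   pair of allocations stops changing — the "agreement" reached at that
   fixed theta.
2. The theta whose agreement maximizes the Nash product
   ``(U_A - U_A^s)(U_B - U_B^s)`` is selected, subject to both members being
   no worse off than at the theta = 0 agreement (the separate-spheres threat
   point, which defines each member's bargaining power).

The search is over discrete grids: allocations on an alpha grid (default
step 0.01), transfers on a theta grid (default step 0.05) searched in both
directions.  All numeric kernels broadcast over arbitrary leading axes so
the simulation engine can solve every household and every candidate theta
simultaneously; the per-household functions below are thin wrappers over
the same kernels.  ``brute_force_bargain`` is an independent exhaustive
oracle used in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import (
    AgentParams,
    Allocation,
    Bargain,
    Direction,
    Gender,
    Household,
    Role,
    utility_member,
)
from .norms import NormState

__all__ = [
    "SolverSettings",
    "ThreatPoint",
    "best_response",
    "equilibrium_at_theta",
    "threat_point",
    "select_bargain",
    "brute_force_bargain",
]

# utilities within this of the maximum count as tied (utilities are O(1))
_TIE_EPS = 1e-12
# Nash products within this of the maximum count as tied
_PROD_TIE_EPS = 1e-15


@dataclass(frozen=True)
class SolverSettings:
    """Grid resolutions and iteration limits for the bargain solver.

    alpha_grid_step : spacing of the time-allocation grid on [0, 1].
    theta_grid_step : spacing of the transfer grid on [0, 1] (searched in
        both directions).
    max_iterations : cap on alternating best-response rounds per theta.
    convergence_tol : maximum allocation change still declaring convergence
        (exact repetition on grids; the tolerance matters only for
        continuous refinements).
    constraint_tol : slack allowed on the participation constraints.
    """

    alpha_grid_step: float = 0.01
    theta_grid_step: float = 0.05
    max_iterations: int = 100
    convergence_tol: float = 1e-6
    constraint_tol: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("alpha_grid_step", "theta_grid_step"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol < 0 or self.constraint_tol < 0:
            raise ValueError("tolerances must be >= 0")

    def alpha_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.alpha_grid_step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 12)

    def theta_grid(self) -> np.ndarray:
        """Transfer magnitudes 0..1."""
        n = int(round(1.0 / self.theta_grid_step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 12)

    def theta_signed_grid(self) -> np.ndarray:
        """Signed transfers: negative = B->A, positive = A->B, one zero."""
        mag = self.theta_grid()
        return np.concatenate([-mag[:0:-1], mag])


@dataclass(frozen=True)
class ThreatPoint:
    """Member utilities at the theta = 0 (separate spheres) agreement."""

    utility_A: float
    utility_B: float


# ---------------------------------------------------------------------------
# broadcastable utility kernels
# ---------------------------------------------------------------------------

def _norm_factor(alpha, theta_mag, conf, mu, include_theta: bool = True):
    """exp(-N) for an agent at behaviour (alpha, 1-alpha, theta_mag).

    ``conf`` and ``mu`` are (c_alpha, c_gamma, c_theta) and the matching
    norm means; each entry broadcasts against ``alpha``.
    """
    n = conf[0] * (alpha - mu[0]) ** 2 + conf[1] * ((1.0 - alpha) - mu[1]) ** 2
    if include_theta:
        n = n + conf[2] * (theta_mag - mu[2]) ** 2
    return np.exp(-n)


def _utility_A(alpha_A, alpha_B, theta_signed, w_A, w_B, p_A, conf_A, mu_A):
    """Member A's utility; broadcasts over all arguments."""
    th_out = np.maximum(theta_signed, 0.0)   # A is transferor
    th_in = np.maximum(-theta_signed, 0.0)   # A is transferee
    priv = w_A * alpha_A * (1.0 - th_out) + th_in * w_B * alpha_B
    pub = (1.0 - alpha_A) + (1.0 - alpha_B)
    goods = p_A * np.sqrt(np.maximum(priv, 0.0)) + (1.0 - p_A) * np.sqrt(pub)
    return goods * _norm_factor(alpha_A, np.abs(theta_signed), conf_A, mu_A)


def _utility_B(alpha_A, alpha_B, theta_signed, w_A, w_B, p_B, conf_B, mu_B):
    """Member B's utility (mirror of A: positive theta flows A->B)."""
    th_in = np.maximum(theta_signed, 0.0)
    th_out = np.maximum(-theta_signed, 0.0)
    priv = w_B * alpha_B * (1.0 - th_out) + th_in * w_A * alpha_A
    pub = (1.0 - alpha_A) + (1.0 - alpha_B)
    goods = p_B * np.sqrt(np.maximum(priv, 0.0)) + (1.0 - p_B) * np.sqrt(pub)
    return goods * _norm_factor(alpha_B, np.abs(theta_signed), conf_B, mu_B)


def _argmax_tiebreak(util, grid, prev):
    """Argmax over the last axis with deterministic tie-breaking.

    Among grid points whose utility is within ``_TIE_EPS`` of the maximum,
    pick the one closest to ``prev`` (the agent's current allocation), then
    the smaller grid value.  ``util`` has shape (..., G); ``prev`` (...,).
    """
    umax = np.max(util, axis=-1, keepdims=True)
    tied = util >= umax - _TIE_EPS
    # grid spacing >= 1e-6 in practice, so the 1e-9 lexicographic term can
    # reorder only exact-distance ties
    key = np.abs(grid - np.asarray(prev)[..., None]) + 1e-9 * grid
    key = np.where(tied, key, np.inf)
    return grid[np.argmin(key, axis=-1)]


def _expand(x):
    """As float array with a trailing grid axis added for broadcasting."""
    return np.asarray(x, dtype=float)[..., None]


def _iterate_equilibria(alpha_A, alpha_B, theta_signed, w_A, w_B,
                        p_A, p_B, conf_A, conf_B, mu_A, mu_B,
                        settings: SolverSettings):
    """Alternate best responses (A first) for every (..., theta) cell.

    ``alpha_A``/``alpha_B`` are warm-start arrays of any shape S that
    broadcasts with ``theta_signed``; per-member parameter arrays broadcast
    against S.  Returns (alpha_A, alpha_B, converged_mask).
    """
    grid = settings.alpha_grid()
    a_A = np.array(alpha_A, dtype=float, copy=True)
    a_B = np.array(alpha_B, dtype=float, copy=True)
    thx, wAx, wBx = _expand(theta_signed), _expand(w_A), _expand(w_B)
    pAx, pBx = _expand(p_A), _expand(p_B)
    confAx = [_expand(c) for c in conf_A]
    confBx = [_expand(c) for c in conf_B]
    muAx = [_expand(m) for m in mu_A]
    muBx = [_expand(m) for m in mu_B]
    converged = np.zeros(np.broadcast(a_A, np.asarray(theta_signed)).shape,
                         dtype=bool)
    for _ in range(settings.max_iterations):
        u_A = _utility_A(grid, _expand(a_B), thx, wAx, wBx, pAx, confAx, muAx)
        new_A = _argmax_tiebreak(u_A, grid, a_A)
        u_B = _utility_B(_expand(new_A), grid, thx, wAx, wBx, pBx, confBx, muBx)
        new_B = _argmax_tiebreak(u_B, grid, a_B)
        unchanged = (np.abs(new_A - a_A) <= settings.convergence_tol) & (
            np.abs(new_B - a_B) <= settings.convergence_tol
        )
        a_A, a_B = new_A, new_B
        converged = unchanged
        if bool(np.all(unchanged)):
            break
    return a_A, a_B, converged


def _member_arrays(params: AgentParams, norm: NormState | None):
    conf = [
        np.float64(params.conformity.get(k, 0.0))
        for k in ("alpha", "gamma", "theta")
    ]
    if norm is None:
        mu = [np.float64(0.0)] * 3
        conf = [np.float64(0.0)] * 3
    else:
        mu = [np.float64(norm.means.get(k, 0.0))
              for k in ("alpha", "gamma", "theta")]
    return conf, mu


def _household_arrays(household: Household, norms: Mapping[Gender, NormState]):
    pa, pb = household.params_A, household.params_B
    conf_A, mu_A = _member_arrays(pa, norms.get(pa.gender))
    conf_B, mu_B = _member_arrays(pb, norms.get(pb.gender))
    return (np.float64(pa.wage), np.float64(pb.wage),
            np.float64(pa.p_alpha), np.float64(pb.p_alpha),
            conf_A, conf_B, mu_A, mu_B)


# ---------------------------------------------------------------------------
# per-household operations
# ---------------------------------------------------------------------------

def best_response(
    role: Role,
    partner_gamma: float,
    theta_signed: float,
    params: AgentParams,
    partner_params: AgentParams,
    norm: NormState | None,
    settings: SolverSettings,
    prev_alpha: float = 0.0,
) -> Allocation:
    """The allocation maximizing one member's utility.

    Holds the partner's public-time contribution and the (signed) transfer
    fixed and searches the alpha grid; ties go to the allocation closest to
    ``prev_alpha``, then to the smaller alpha.  ``theta_signed`` is positive
    for direction A->B regardless of ``role``.
    """
    grid = settings.alpha_grid()
    conf, mu = _member_arrays(params, norm)
    th = np.float64(theta_signed)
    partner_alpha = np.float64(1.0 - partner_gamma)
    if role is Role.A:
        util = _utility_A(grid, partner_alpha, th,
                          np.float64(params.wage), np.float64(partner_params.wage),
                          np.float64(params.p_alpha), conf, mu)
    else:
        util = _utility_B(partner_alpha, grid, th,
                          np.float64(partner_params.wage), np.float64(params.wage),
                          np.float64(params.p_alpha), conf, mu)
    alpha = float(_argmax_tiebreak(util, grid, np.float64(prev_alpha)))
    return Allocation.from_alpha(alpha)


def equilibrium_at_theta(
    household: Household,
    theta_signed: float,
    norms: Mapping[Gender, NormState],
    settings: SolverSettings,
) -> tuple[Bargain, bool]:
    """Converged alternating-best-response agreement at a fixed transfer.

    Returns the bargain and a flag that is False when the iteration hit
    ``max_iterations`` without repeating (the last iterate is still
    returned; callers log the flag).
    """
    if not -1.0 - 1e-12 <= theta_signed <= 1.0 + 1e-12:
        raise ValueError("theta magnitude must lie in [0, 1]")
    w_A, w_B, p_A, p_B, conf_A, conf_B, mu_A, mu_B = _household_arrays(
        household, norms
    )
    prev = household.prev_bargain
    a0_A = prev.alloc_A.alpha if prev is not None else 0.0
    a0_B = prev.alloc_B.alpha if prev is not None else 0.0
    a_A, a_B, conv = _iterate_equilibria(
        np.float64(a0_A), np.float64(a0_B), np.float64(theta_signed),
        w_A, w_B, p_A, p_B, conf_A, conf_B, mu_A, mu_B, settings,
    )
    return Bargain.from_signed(float(a_A), float(a_B), theta_signed), bool(conv)


def threat_point(
    household: Household,
    norms: Mapping[Gender, NormState],
    settings: SolverSettings,
) -> ThreatPoint:
    """Member utilities at the theta = 0 agreement (bargaining power)."""
    bargain, _ = equilibrium_at_theta(household, 0.0, norms, settings)
    u_A = utility_member(Role.A, bargain, household.params_A,
                         household.params_B, norms.get(household.params_A.gender))
    u_B = utility_member(Role.B, bargain, household.params_A,
                         household.params_B, norms.get(household.params_B.gender))
    return ThreatPoint(utility_A=u_A, utility_B=u_B)


def select_bargain(
    household: Household,
    norms: Mapping[Gender, NormState],
    settings: SolverSettings,
) -> Bargain:
    """The household's bargain for this time step.

    Computes the agreement at every grid transfer in both directions and
    returns the one maximizing the Nash product of utility gains over the
    separate-spheres threat point, subject to both members gaining (up to
    ``constraint_tol``).  If no non-zero transfer satisfies the constraints
    the theta = 0 agreement is returned.  Ties break toward the smaller
    transfer magnitude, then toward the previous step's direction.
    """
    res = _select_bargains_batch([household], norms, settings)
    return res.bargains[0]


@dataclass
class BatchResult:
    bargains: list[Bargain]
    utilities_A: np.ndarray
    utilities_B: np.ndarray
    n_nonconverged: int
    # converged per-(household, theta) allocations, reusable as the next
    # step's warm start
    eq_alpha_A: np.ndarray | None = None
    eq_alpha_B: np.ndarray | None = None


def _select_bargains_batch(
    households: list[Household],
    norms: Mapping[Gender, NormState],
    settings: SolverSettings,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> BatchResult:
    """Vectorized :func:`select_bargain` over many households.

    ``warm_start`` optionally carries per-(household, theta) allocation
    arrays from the previous time step to speed convergence; the result's
    bargains are independent of the warm start whenever the alternating
    best-response map has a unique attractor from both starts (tested on
    fixtures).
    """
    H = len(households)
    th = settings.theta_signed_grid()            # (T,)
    T = th.size

    def col(f):
        return np.array([f(h) for h in households], dtype=float)

    w_A = col(lambda h: h.params_A.wage)[:, None]
    w_B = col(lambda h: h.params_B.wage)[:, None]
    p_A = col(lambda h: h.params_A.p_alpha)[:, None]
    p_B = col(lambda h: h.params_B.p_alpha)[:, None]

    def conf_mu(side):
        confs, mus = [], []
        for h in households:
            params = h.params_A if side == "A" else h.params_B
            c, m = _member_arrays(params, norms.get(params.gender))
            confs.append(c)
            mus.append(m)
        conf = [np.array([c[i] for c in confs])[:, None] for i in range(3)]
        mu = [np.array([m[i] for m in mus])[:, None] for i in range(3)]
        return conf, mu

    conf_A, mu_A = conf_mu("A")
    conf_B, mu_B = conf_mu("B")

    if warm_start is not None:
        a_A0, a_B0 = warm_start
    else:
        a_A0 = np.tile(
            col(lambda h: h.prev_bargain.alloc_A.alpha if h.prev_bargain else 0.0)
            [:, None], (1, T))
        a_B0 = np.tile(
            col(lambda h: h.prev_bargain.alloc_B.alpha if h.prev_bargain else 0.0)
            [:, None], (1, T))

    theta = np.broadcast_to(th[None, :], (H, T))
    a_A, a_B, conv = _iterate_equilibria(
        a_A0, a_B0, theta, w_A, w_B, p_A, p_B, conf_A, conf_B,
        mu_A, mu_B, settings,
    )

    u_A = _utility_A(a_A, a_B, theta, w_A, w_B, p_A, conf_A, mu_A)
    u_B = _utility_B(a_A, a_B, theta, w_A, w_B, p_B, conf_B, mu_B)

    i0 = T // 2                                   # index of theta == 0
    gain_A = u_A - u_A[:, i0][:, None]
    gain_B = u_B - u_B[:, i0][:, None]
    feasible = (gain_A >= -settings.constraint_tol) & (
        gain_B >= -settings.constraint_tol
    )
    prod = np.where(feasible, gain_A * gain_B, -np.inf)

    prev_dir = col(
        lambda h: (h.prev_bargain.theta_signed > 0) - (h.prev_bargain.theta_signed < 0)
        if h.prev_bargain is not None else 0
    )
    best = prod.max(axis=1)
    tied = prod >= best[:, None] - _PROD_TIE_EPS
    sign = np.sign(th)[None, :]
    # |theta| spacing >= theta_grid_step, so the small penalties only break
    # exact |theta| ties: first toward the previous direction, then A->B
    rank = np.abs(th)[None, :] \
        + 1e-6 * (sign != prev_dir[:, None]) \
        + 1e-9 * (sign < 0)
    rank = np.where(tied, rank, np.inf)
    sel = np.argmin(rank, axis=1)

    rows = np.arange(H)
    bargains = [
        Bargain.from_signed(a_A[h, s], a_B[h, s], th[s])
        for h, s in zip(rows, sel)
    ]
    n_bad = int(np.sum(~conv))
    return BatchResult(
        bargains=bargains,
        utilities_A=u_A[rows, sel],
        utilities_B=u_B[rows, sel],
        n_nonconverged=n_bad,
        eq_alpha_A=a_A,
        eq_alpha_B=a_B,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

_MAX_BRUTE_POINTS = 51 * 51 * (21 * 2 - 1)


def brute_force_bargain(
    household: Household,
    norms: Mapping[Gender, NormState],
    settings: SolverSettings,
) -> Bargain:
    """Exhaustive Nash-product search on coarse grids (test oracle).

    Evaluates both members' utilities directly at every joint
    ``(alpha_A, alpha_B, signed theta)`` grid point — no best-response
    iteration for the candidates — keeping points where both members gain
    over the separate-spheres threat point, and returns the feasible
    argmax of the Nash product.  If no non-zero transfer is feasible the
    theta = 0 agreement is returned.  Guarded against fine grids: intended
    for coarse verification only.
    """
    grid = settings.alpha_grid()
    th = settings.theta_signed_grid()
    n_points = grid.size * grid.size * th.size
    if n_points > _MAX_BRUTE_POINTS:
        raise ValueError(
            f"brute-force grid of {n_points} points exceeds the "
            f"{_MAX_BRUTE_POINTS} guard; coarsen the settings"
        )

    tp = threat_point(household, norms, settings)
    base, _ = equilibrium_at_theta(household, 0.0, norms, settings)

    pa, pb = household.params_A, household.params_B
    norm_A = norms.get(pa.gender)
    norm_B = norms.get(pb.gender)

    best_prod = 0.0
    best = base
    best_absth = 0.0
    for t in th:
        if t == 0.0:
            continue
        for a_A in grid:
            for a_B in grid:
                bargain = Bargain.from_signed(float(a_A), float(a_B), float(t))
                u_A = utility_member(Role.A, bargain, pa, pb, norm_A)
                u_B = utility_member(Role.B, bargain, pa, pb, norm_B)
                g_A = u_A - tp.utility_A
                g_B = u_B - tp.utility_B
                if g_A < -settings.constraint_tol or g_B < -settings.constraint_tol:
                    continue
                prod = g_A * g_B
                if prod > best_prod + _PROD_TIE_EPS or (
                    prod > best_prod - _PROD_TIE_EPS and abs(t) < best_absth
                ):
                    best_prod = prod
                    best = bargain
                    best_absth = abs(t)
    return best


def nash_product(
    bargain: Bargain,
    household: Household,
    norms: Mapping[Gender, NormState],
    threat: ThreatPoint,
) -> float:
    """Nash product of utility gains at a bargain, given a threat point."""
    u_A = utility_member(Role.A, bargain, household.params_A,
                         household.params_B, norms.get(household.params_A.gender))
    u_B = utility_member(Role.B, bargain, household.params_A,
                         household.params_B, norms.get(household.params_B.gender))
    return (u_A - threat.utility_A) * (u_B - threat.utility_B)
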