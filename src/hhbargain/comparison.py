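"""Individual-based (IM) and unitary-household (UM) comparison models.

Both strip out the bargain.  An IM agent maximizes its own utility using
only its own time (its public good comes from its own public hours); a UM
household maximizes a single household utility over both members' time with
pooled private output, but keeps gender-specific wages and sums both
members' norm penalties.  Neither model has a transfer, so their norms
track only the ``alpha`` and ``gamma`` components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import AgentParams, Allocation, Gender, Household
from .norms import NormState
from .bargaining import SolverSettings, _TIE_EPS

__all__ = ["HouseholdPrefs", "im_solve", "um_household_prefs", "um_solve"]


@dataclass(frozen=True)
class HouseholdPrefs:
    """The single preference pair a unitary household optimizes with."""

    p_alpha_H: float
    p_gamma_H: float

    def __post_init__(self) -> None:
        if not math.isclose(self.p_alpha_H + self.p_gamma_H, 1.0, abs_tol=1e-12):
            raise ValueError("household preference weights must sum to 1")


def _im_utility_grid(alpha, p, w, conf_a, conf_g, mu_a, mu_g):
    goods = p * np.sqrt(w * alpha) + (1.0 - p) * np.sqrt(1.0 - alpha)
    n = conf_a * (alpha - mu_a) ** 2 + conf_g * ((1.0 - alpha) - mu_g) ** 2
    return goods * np.exp(-n)


def im_solve(
    params: AgentParams,
    norm: NormState | None,
    settings: SolverSettings,
    prev_alpha: float = 0.0,
) -> Allocation:
    """One agent's individually optimal allocation.

    Maximizes ``p_a sqrt(w a) + p_g sqrt(1 - a)`` times the norm factor over
    the alpha grid; ties go to the allocation closest to ``prev_alpha``,
    then the smaller alpha.  At zero conformity the continuous optimum has
    the closed form ``a* = p^2 w / ((1-p)^2 + p^2 w)``.
    """
    grid = settings.alpha_grid()
    mu_a = norm.means["alpha"] if norm is not None else 0.0
    mu_g = norm.means["gamma"] if norm is not None else 0.0
    c_a = params.conformity.get("alpha", 0.0) if norm is not None else 0.0
    c_g = params.conformity.get("gamma", 0.0) if norm is not None else 0.0
    util = _im_utility_grid(grid, params.p_alpha, params.wage, c_a, c_g, mu_a, mu_g)
    umax = util.max()
    tied = util >= umax - _TIE_EPS
    key = np.abs(grid - prev_alpha) + 1e-9 * grid
    key = np.where(tied, key, np.inf)
    return Allocation.from_alpha(float(grid[int(np.argmin(key))]))


def um_household_prefs(
    params_A: AgentParams,
    params_B: AgentParams,
    rule: str = "mean",
) -> HouseholdPrefs:
    """Build the unitary household's single preference pair from its members.

    ``rule='mean'`` averages the members' private-good weights;
    ``rule='head_male'`` adopts the male member's weights (the classic
    household-head reading).
    """
    if rule == "mean":
        p = (params_A.p_alpha + params_B.p_alpha) / 2.0
    elif rule == "head_male":
        head = params_A if params_A.gender is Gender.MALE else params_B
        p = head.p_alpha
    else:
        raise ValueError(f"unknown um_pref_rule {rule!r}")
    return HouseholdPrefs(p_alpha_H=p, p_gamma_H=1.0 - p)


def um_utility_grid(alpha_A, alpha_B, w_A, w_B, p_H,
                    conf_A, conf_B, mu_A, mu_B):
    """Unitary household utility; broadcasts over allocation arrays.

    ``conf_*`` are (c_alpha, c_gamma) pairs and ``mu_*`` the matching
    gender-norm means for each member; penalties are summed over members.
    """
    priv = w_A * alpha_A + w_B * alpha_B
    pub = (1.0 - alpha_A) + (1.0 - alpha_B)
    goods = p_H * np.sqrt(priv) + (1.0 - p_H) * np.sqrt(pub)
    n = (
        conf_A[0] * (alpha_A - mu_A[0]) ** 2
        + conf_A[1] * ((1.0 - alpha_A) - mu_A[1]) ** 2
        + conf_B[0] * (alpha_B - mu_B[0]) ** 2
        + conf_B[1] * ((1.0 - alpha_B) - mu_B[1]) ** 2
    )
    return goods * np.exp(-n)


def um_solve(
    household: Household,
    prefs: HouseholdPrefs,
    norms: Mapping[Gender, NormState],
    settings: SolverSettings,
    prev: tuple[float, float] = (0.0, 0.0),
) -> tuple[Allocation, Allocation]:
    """The unitary household's jointly optimal pair of allocations.

    Searches the joint (alpha_A, alpha_B) grid; ties go to the pair closest
    (L1) to the previous step's pair, then to the lexicographically smaller
    (alpha_A, alpha_B).
    """
    grid = settings.alpha_grid()
    pa, pb = household.params_A, household.params_B

    def cm(params):
        norm = norms.get(params.gender)
        if norm is None:
            return (0.0, 0.0), (0.0, 0.0)
        conf = (params.conformity.get("alpha", 0.0),
                params.conformity.get("gamma", 0.0))
        mu = (norm.means["alpha"], norm.means["gamma"])
        return conf, mu

    conf_A, mu_A = cm(pa)
    conf_B, mu_B = cm(pb)
    util = um_utility_grid(grid[:, None], grid[None, :],
                           pa.wage, pb.wage, prefs.p_alpha_H,
                           conf_A, conf_B, mu_A, mu_B)
    umax = util.max()
    tied = util >= umax - _TIE_EPS
    # L1 distance resolves in grid-step quanta; the tiny terms only break
    # exact-distance ties lexicographically
    key = (np.abs(grid[:, None] - prev[0]) + np.abs(grid[None, :] - prev[1])
           + 1e-7 * grid[:, None] + 1e-9 * grid[None, :])
    key = np.where(tied, key, np.inf)
    i, j = np.unravel_index(int(np.argmin(key)), util.shape)
    return (Allocation.from_alpha(float(grid[i])),
            Allocation.from_alpha(float(grid[j])))
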