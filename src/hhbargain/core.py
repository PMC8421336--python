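"""Domain types and utility functions of the intra-household model.

A two-member household (members labelled A and B) divides each member's
unit time budget between a *private* activity (wage work, output consumed
individually and transferable between spouses) and a *public* activity
(e.g. housework, output shared by both members).  Member utility is a
preference-weighted sum of square-rooted goods, discounted by a social-norm
conformity factor ``exp(-N)`` computed in :mod:`hhbargain.norms`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "Gender",
    "Direction",
    "Role",
    "AgentParams",
    "Allocation",
    "Bargain",
    "GoodsBundle",
    "Household",
    "NORM_COMPONENTS",
    "private_output",
    "public_output",
    "utility_member",
]

#: Behaviour components a gender norm may track.
NORM_COMPONENTS = ("alpha", "gamma", "theta")


class Gender(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Direction(str, enum.Enum):
    """Direction of the private-good transfer within a household."""

    A_TO_B = "A_to_B"
    B_TO_A = "B_to_A"
    NONE = "none"


class Role(str, enum.Enum):
    A = "A"
    B = "B"


@dataclass(frozen=True)
class AgentParams:
    """Fixed attributes of one agent.

    Parameters
    ----------
    agent_id:
        Unique identifier.
    gender:
        Determines the norm population the agent subscribes to and which
        wage schedule applies.
    p_alpha, p_gamma:
        Preference weights for the private and public good; must sum to 1.
    conformity:
        Non-negative weight per norm component (``alpha``, ``gamma``,
        ``theta``): how strongly the agent prefers matching its population's
        mean behaviour over goods consumption.
    wage:
        Private-good output per unit of time spent on the private activity.
        Time-varying through the simulation schedule.
    """

    agent_id: str
    gender: Gender
    p_alpha: float
    p_gamma: float
    conformity: Mapping[str, float]
    wage: float

    def __post_init__(self) -> None:
        if not math.isclose(self.p_alpha + self.p_gamma, 1.0, abs_tol=1e-12):
            raise ValueError("p_alpha + p_gamma must equal 1")
        if not 0.0 <= self.p_alpha <= 1.0:
            raise ValueError("p_alpha must lie in [0, 1]")
        if any(c < 0 for c in self.conformity.values()):
            raise ValueError("conformity weights must be >= 0")
        if self.wage <= 0:
            raise ValueError("wage must be > 0")


@dataclass(frozen=True)
class Allocation:
    """One member's split of unit time: ``alpha`` private, ``gamma`` public."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.alpha <= 1 + 1e-9:
            raise ValueError("alpha must lie in [0, 1]")
        if not math.isclose(self.alpha + self.gamma, 1.0, abs_tol=1e-9):
            raise ValueError("alpha + gamma must equal 1 (unit time budget)")

    @classmethod
    def from_alpha(cls, alpha: float) -> "Allocation":
        return cls(alpha=alpha, gamma=1.0 - alpha)


@dataclass(frozen=True)
class Bargain:
    """A household's joint decision: both allocations plus the transfer.

    ``theta`` is the fraction of the transferor's private output handed to
    the other member; ``direction`` says who transfers.  ``theta == 0``
    if and only if ``direction`` is :attr:`Direction.NONE` (the
    "separate spheres" outcome).
    """

    alloc_A: Allocation
    alloc_B: Allocation
    theta: float
    direction: Direction

    def __post_init__(self) -> None:
        if not -1e-12 <= self.theta <= 1 + 1e-12:
            raise ValueError("theta must lie in [0, 1]")
        if (self.theta == 0) != (self.direction is Direction.NONE):
            raise ValueError("theta == 0 iff direction is NONE")

    @property
    def theta_signed(self) -> float:
        """Signed transfer: positive A->B, negative B->A."""
        if self.direction is Direction.B_TO_A:
            return -self.theta
        return self.theta

    @classmethod
    def from_signed(
        cls, alpha_A: float, alpha_B: float, theta_signed: float
    ) -> "Bargain":
        if theta_signed > 0:
            direction = Direction.A_TO_B
        elif theta_signed < 0:
            direction = Direction.B_TO_A
        else:
            direction = Direction.NONE
        return cls(
            alloc_A=Allocation.from_alpha(alpha_A),
            alloc_B=Allocation.from_alpha(alpha_B),
            theta=abs(theta_signed),
            direction=direction,
        )


@dataclass(frozen=True)
class GoodsBundle:
    """Non-negative amounts of private and public good."""

    private_good: float
    public_good: float

    def __post_init__(self) -> None:
        if self.private_good < 0 or self.public_good < 0:
            raise ValueError("goods amounts must be >= 0")


@dataclass
class Household:
    """An A/B member pair with the bargain currently in force.

    ``prev_bargain`` is used for tie-breaking (behavioural inertia) when
    the bargaining objective is flat.
    """

    params_A: AgentParams
    params_B: AgentParams
    prev_bargain: Bargain | None = None
    household_id: str = field(default="h0")


def private_output(alpha: float, wage: float) -> float:
    """Private-good output of one member: a linear wage, ``wage * alpha``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if wage <= 0:
        raise ValueError("wage must be > 0")
    return wage * alpha


def public_output(gamma_A: float, gamma_B: float) -> float:
    """Public-good output from pooled time; both members receive this amount."""
    for g in (gamma_A, gamma_B):
        if not 0.0 <= g <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
    return gamma_A + gamma_B


def utility_member(
    role: Role,
    bargain: Bargain,
    params_A: AgentParams,
    params_B: AgentParams,
    norm: "NormState | None" = None,
) -> float:
    """Utility of one household member at a candidate bargain.

    For member A with transfer direction A->B::

        U_A = [p_a^A * sqrt(w_A a_A (1 - theta)) + p_g^A * sqrt(g_A + g_B)] * exp(-N)

    and B's private radicand gains the transferred amount
    ``theta * w_A * a_A + w_B * a_B``.  The mirrored formulas apply for
    direction B->A.  ``N`` is the conformity-weighted squared distance of the
    member's own behaviours (own alpha, own gamma, household theta magnitude)
    from its norm-population means; ``norm=None`` means no norm pressure
    (factor exactly 1).
    """
    # local import avoids a cycle (norms imports nothing from here)
    from .norms import norm_penalty

    a_A, a_B = bargain.alloc_A.alpha, bargain.alloc_B.alpha
    g_A, g_B = bargain.alloc_A.gamma, bargain.alloc_B.gamma
    out_A = private_output(a_A, params_A.wage) if a_A > 0 else 0.0
    out_B = private_output(a_B, params_B.wage) if a_B > 0 else 0.0
    th = bargain.theta

    if role is Role.A:
        own, p = params_A, params_A.p_alpha
        if bargain.direction is Direction.B_TO_A:
            priv = out_A + th * out_B
        else:
            priv = out_A * (1.0 - th)
        own_alpha, own_gamma = a_A, g_A
    else:
        own, p = params_B, params_B.p_alpha
        if bargain.direction is Direction.A_TO_B:
            priv = out_B + th * out_A
        else:
            priv = out_B * (1.0 - th)
        own_alpha, own_gamma = a_B, g_B

    goods = p * math.sqrt(max(priv, 0.0)) + (1.0 - p) * math.sqrt(
        public_output(g_A, g_B)
    )
    if norm is None:
        return goods

    behaviors = {"alpha": own_alpha, "gamma": own_gamma}
    if "theta" in norm.means:
        behaviors["theta"] = th
    _, factor = norm_penalty(behaviors, norm, own.conformity)
    return goods * factor
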