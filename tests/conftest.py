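"""Shared fixtures: deterministic micro-populations and parameter factories."""

from __future__ import annotations

import numpy as np
import pytest

from hhbargain import AgentParams, Gender, Household


def make_agent(
    agent_id: str = "f000",
    gender: Gender = Gender.FEMALE,
    p_alpha: float = 0.5,
    conformity: float | dict = 0.0,
    wage: float = 0.6,
) -> AgentParams:
    if not isinstance(conformity, dict):
        conformity = {"alpha": conformity, "gamma": conformity,
                      "theta": conformity}
    return AgentParams(
        agent_id=agent_id,
        gender=gender,
        p_alpha=p_alpha,
        p_gamma=1.0 - p_alpha,
        conformity=conformity,
        wage=wage,
    )


def make_household(
    p_alpha_A: float = 0.5,
    p_alpha_B: float = 0.5,
    w_A: float = 0.1,
    w_B: float = 0.6,
    conformity: float = 0.0,
) -> Household:
    return Household(
        params_A=make_agent("f000", Gender.FEMALE, p_alpha_A, conformity, w_A),
        params_B=make_agent("m000", Gender.MALE, p_alpha_B, conformity, w_B),
    )


def random_household(rng: np.random.Generator) -> Household:
    """A household with the distributions the experiments sample from."""
    p = rng.uniform(0.3, 0.7, 2)
    c = rng.uniform(0.3, 0.7, (2, 3))
    return Household(
        params_A=make_agent(
            "f000", Gender.FEMALE, float(p[0]),
            {"alpha": c[0, 0], "gamma": c[0, 1], "theta": c[0, 2]},
            wage=float(rng.uniform(0.1, 1.1)),
        ),
        params_B=make_agent(
            "m000", Gender.MALE, float(p[1]),
            {"alpha": c[1, 0], "gamma": c[1, 1], "theta": c[1, 2]},
            wage=float(rng.uniform(0.1, 1.1)),
        ),
    )


@pytest.fixture
def zero_conf_household() -> Household:
    return make_household()
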