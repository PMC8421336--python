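"""Population construction, parameter sampling, and the simulation loop.

A simulation pairs ``n_agents/2`` female agents with ``n_agents/2`` male
agents into households, initializes allocations to the traditional gender
roles (males 80% private activity, females 20%), runs the chosen decision
model once per time step for every household (or individual, for the
individual-based model), and updates the two gender norms from the
just-completed step's behaviours.  The only random draws are the agent
parameters at setup; the dynamics themselves are deterministic, so a run is
exactly reproducible from its seed.

The schedule: female wage starts at ``w_f_pre`` and jumps to ``w_f_post``
at step ``t_change`` (decisions at ``t_change`` already use the new wage);
under the conformist-males (CM) condition the high conformity draws are
applied at the same moment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AgentParams, Bargain, Direction, Gender, Household
from .norms import NormState, update_norms
from .bargaining import SolverSettings, _select_bargains_batch, _TIE_EPS
from .comparison import (
    HouseholdPrefs,
    um_household_prefs,
    um_utility_grid,
    _im_utility_grid,
)

__all__ = [
    "ModelConfig",
    "SimulationState",
    "sample_parameters",
    "init_population",
    "apply_change_event",
    "step",
    "run",
]

MODELS = ("ihm", "im", "um")
CONDITIONS = ("mp", "cm")

#: Uniform ranges for moderate parameters and for CM high male conformity.
MODERATE_RANGE = (0.3, 0.7)
HIGH_CONFORMITY_RANGE = (2.5, 3.0)

#: Initial share of time on the private activity, by gender.
INIT_ALPHA = {Gender.MALE: 0.8, Gender.FEMALE: 0.2}

_DIR_CODE = {-1: Direction.B_TO_A, 0: Direction.NONE, 1: Direction.A_TO_B}


@dataclass(frozen=True)
class ModelConfig:
    """Full specification of one simulation run."""

    model: str = "ihm"
    condition: str = "mp"
    w_f_post: float = 1.1
    n_agents: int = 200
    t_change: int = 25
    t_end: int = 150
    w_m: float = 0.6
    w_f_pre: float = 0.1
    seed: int = 0
    solver: SolverSettings = field(default_factory=SolverSettings)
    um_pref_rule: str = "mean"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.n_agents < 2 or self.n_agents % 2:
            raise ValueError("n_agents must be even and >= 2")
        if not 0 < self.t_change < self.t_end:
            raise ValueError("need 0 < t_change < t_end")
        for w in (self.w_m, self.w_f_pre, self.w_f_post):
            if w <= 0:
                raise ValueError("wages must be > 0")
        if self.um_pref_rule not in ("mean", "head_male"):
            raise ValueError("um_pref_rule must be 'mean' or 'head_male'")


def sample_parameters(
    condition: str,
    n_agents: int,
    seed: int,
    w_f: float = 0.1,
    w_m: float = 0.6,
) -> tuple[list[AgentParams], dict[str, dict[str, float]]]:
    """Draw a population of agents, reproducibly from ``seed``.

    The first half are female, the second half male.  Private-good
    preference and every conformity component are drawn from U(0.3, 0.7).
    High conformity replacements (U(2.5, 3.0)) are drawn for every agent in
    the same pass — so populations are identical across models and
    conditions for a given seed — and returned separately; the change event
    applies them only where the condition and model call for it.
    """
    if n_agents < 2 or n_agents % 2:
        raise ValueError("n_agents must be even and >= 2")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    lo, hi = MODERATE_RANGE
    p_alpha = rng.uniform(lo, hi, n_agents)
    conf = rng.uniform(lo, hi, (n_agents, 3))
    conf_high = rng.uniform(*HIGH_CONFORMITY_RANGE, (n_agents, 3))

    half = n_agents // 2
    agents: list[AgentParams] = []
    high: dict[str, dict[str, float]] = {}
    for i in range(n_agents):
        female = i < half
        gender = Gender.FEMALE if female else Gender.MALE
        agent_id = f"f{i:03d}" if female else f"m{i - half:03d}"
        agents.append(
            AgentParams(
                agent_id=agent_id,
                gender=gender,
                p_alpha=float(p_alpha[i]),
                p_gamma=float(1.0 - p_alpha[i]),
                conformity={
                    "alpha": float(conf[i, 0]),
                    "gamma": float(conf[i, 1]),
                    "theta": float(conf[i, 2]),
                },
                wage=w_f if female else w_m,
            )
        )
        high[agent_id] = {
            "alpha": float(conf_high[i, 0]),
            "gamma": float(conf_high[i, 1]),
            "theta": float(conf_high[i, 2]),
        }
    return agents, high


@dataclass
class SimulationState:
    """Mutable state of a running simulation."""

    config: ModelConfig
    agents: list[AgentParams]
    high_conformity: dict[str, dict[str, float]]
    step: int                      # next step to execute (1-based)
    alpha: np.ndarray              # (n,) current private-activity share
    theta: np.ndarray              # (n_households,) transfer magnitude
    direction: np.ndarray          # (n_households,) -1 B->A, 0, +1 A->B
    norms: dict[Gender, NormState]
    change_applied: bool = False
    eq_alpha_A: np.ndarray | None = None   # warm start, (H, T)
    eq_alpha_B: np.ndarray | None = None
    n_nonconverged: int = 0
    n_household_steps: int = 0
    records: list[dict] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def n_households(self) -> int:
        return len(self.agents) // 2

    def household_members(self, h: int) -> tuple[int, int]:
        """Agent indices of household ``h``: (female, male) = (A, B)."""
        return h, h + self.n_households

    def copy(self) -> "SimulationState":
        return SimulationState(
            config=self.config,
            agents=list(self.agents),
            high_conformity=self.high_conformity,
            step=self.step,
            alpha=self.alpha.copy(),
            theta=self.theta.copy(),
            direction=self.direction.copy(),
            norms={g: dataclasses.replace(n) for g, n in self.norms.items()},
            change_applied=self.change_applied,
            eq_alpha_A=None if self.eq_alpha_A is None else self.eq_alpha_A.copy(),
            eq_alpha_B=None if self.eq_alpha_B is None else self.eq_alpha_B.copy(),
            n_nonconverged=self.n_nonconverged,
            n_household_steps=self.n_household_steps,
            records=list(self.records),
            log=list(self.log),
        )


def _norm_components(model: str) -> tuple[str, ...]:
    return ("alpha", "gamma", "theta") if model == "ihm" else ("alpha", "gamma")


def init_population(
    config: ModelConfig,
    agents: list[AgentParams] | None = None,
    high_conformity: dict[str, dict[str, float]] | None = None,
) -> SimulationState:
    """Sample (or accept) a population and set up the initial state.

    Household ``h`` pairs female ``h`` with male ``h`` (member A is the
    female).  Allocations start at the gendered defaults, transfers at
    zero, and norm means at the population means of those initial values.
    """
    if agents is None:
        agents, high_conformity = sample_parameters(
            config.condition, config.n_agents, config.seed,
            w_f=config.w_f_pre, w_m=config.w_m,
        )
    if high_conformity is None:
        high_conformity = {}
    n = len(agents)
    half = n // 2
    alpha = np.array(
        [INIT_ALPHA[a.gender] for a in agents], dtype=float
    )
    comps = _norm_components(config.model)
    norms = {}
    for gender, sl in ((Gender.FEMALE, slice(0, half)),
                       (Gender.MALE, slice(half, n))):
        means = {"alpha": float(np.mean(alpha[sl])),
                 "gamma": float(np.mean(1.0 - alpha[sl]))}
        if "theta" in comps:
            means["theta"] = 0.0
        norms[gender] = NormState(
            population_id=gender.value,
            means=means,
            membership=frozenset(a.agent_id for a in agents[sl]),
        )
    return SimulationState(
        config=config,
        agents=agents,
        high_conformity=high_conformity,
        step=1,
        alpha=alpha,
        theta=np.zeros(half),
        direction=np.zeros(half, dtype=int),
        norms=norms,
    )


def apply_change_event(state: SimulationState, config: ModelConfig) -> SimulationState:
    """The one-time wage (and, under CM, conformity) change.

    Must be called when the next step to execute is ``t_change``.  Female
    wages become ``w_f_post``; under the CM condition the pre-sampled high
    conformity values replace male agents' weights (for the unitary model:
    both members', since the whole household is the conformist unit there).
    """
    if state.step != config.t_change:
        raise ValueError(
            f"change event applies at step {config.t_change}, not {state.step}"
        )
    if state.change_applied:
        raise ValueError("change event already applied")
    new_agents = []
    for a in state.agents:
        changes: dict = {}
        if a.gender is Gender.FEMALE:
            changes["wage"] = config.w_f_post
        if config.condition == "cm":
            conformist = (
                a.gender is Gender.MALE or config.model == "um"
            )
            if conformist and a.agent_id in state.high_conformity:
                changes["conformity"] = dict(state.high_conformity[a.agent_id])
        new_agents.append(replace(a, **changes) if changes else a)
    state.agents = new_agents
    state.change_applied = True
    state.log.append(f"t={state.step}: wage change applied "
                     f"(w_f -> {config.w_f_post}, condition={config.condition})")
    return state


# ---------------------------------------------------------------------------
# per-model step kernels
# ---------------------------------------------------------------------------

def _households(state: SimulationState) -> list[Household]:
    H = state.n_households
    out = []
    for h in range(H):
        fi, mi = state.household_members(h)
        prev = Bargain.from_signed(
            state.alpha[fi], state.alpha[mi],
            float(state.direction[h]) * float(state.theta[h]),
        )
        out.append(Household(
            params_A=state.agents[fi], params_B=state.agents[mi],
            prev_bargain=prev, household_id=f"h{h:03d}",
        ))
    return out


def _step_ihm(state: SimulationState) -> tuple[np.ndarray, np.ndarray]:
    cfg = state.config
    households = _households(state)
    warm = None
    if state.eq_alpha_A is not None:
        warm = (state.eq_alpha_A, state.eq_alpha_B)
    res = _select_bargains_batch(households, state.norms, cfg.solver,
                                 warm_start=warm)
    H = len(households)
    n = len(state.agents)
    alpha = np.empty(n)
    utility = np.empty(n)
    for h, b in enumerate(res.bargains):
        fi, mi = state.household_members(h)
        alpha[fi] = b.alloc_A.alpha
        alpha[mi] = b.alloc_B.alpha
        state.theta[h] = b.theta
        state.direction[h] = {
            Direction.A_TO_B: 1, Direction.B_TO_A: -1, Direction.NONE: 0
        }[b.direction]
        utility[fi] = res.utilities_A[h]
        utility[mi] = res.utilities_B[h]
    state.eq_alpha_A = res.eq_alpha_A
    state.eq_alpha_B = res.eq_alpha_B
    state.n_nonconverged += res.n_nonconverged
    state.n_household_steps += H
    if res.n_nonconverged:
        state.log.append(
            f"t={state.step}: {res.n_nonconverged} (household, theta) cells "
            "hit max_iterations"
        )
    state.alpha = alpha
    return alpha, utility


def _step_im(state: SimulationState) -> tuple[np.ndarray, np.ndarray]:
    cfg = state.config
    grid = cfg.solver.alpha_grid()
    n = len(state.agents)
    p = np.array([a.p_alpha for a in state.agents])[:, None]
    w = np.array([a.wage for a in state.agents])[:, None]
    c_a = np.array([a.conformity.get("alpha", 0.0) for a in state.agents])[:, None]
    c_g = np.array([a.conformity.get("gamma", 0.0) for a in state.agents])[:, None]
    mu_a = np.array(
        [state.norms[a.gender].means["alpha"] for a in state.agents])[:, None]
    mu_g = np.array(
        [state.norms[a.gender].means["gamma"] for a in state.agents])[:, None]
    util = _im_utility_grid(grid[None, :], p, w, c_a, c_g, mu_a, mu_g)
    umax = util.max(axis=1, keepdims=True)
    tied = util >= umax - _TIE_EPS
    key = np.abs(grid[None, :] - state.alpha[:, None]) + 1e-9 * grid[None, :]
    key = np.where(tied, key, np.inf)
    idx = np.argmin(key, axis=1)
    alpha = grid[idx]
    utility = util[np.arange(n), idx]
    state.alpha = alpha
    state.n_household_steps += state.n_households
    return alpha, utility


def _step_um(state: SimulationState) -> tuple[np.ndarray, np.ndarray]:
    cfg = state.config
    grid = cfg.solver.alpha_grid()
    H = state.n_households
    n = len(state.agents)
    half = H
    fa = state.agents[:half]
    ma = state.agents[half:]
    p_H = np.array([
        um_household_prefs(f, m, cfg.um_pref_rule).p_alpha_H
        for f, m in zip(fa, ma)
    ])[:, None, None]
    w_A = np.array([a.wage for a in fa])[:, None, None]
    w_B = np.array([a.wage for a in ma])[:, None, None]

    def cpair(agents_, comp):
        return np.array([a.conformity.get(comp, 0.0) for a in agents_])[:, None, None]

    mu_F = state.norms[Gender.FEMALE].means
    mu_M = state.norms[Gender.MALE].means
    util = um_utility_grid(
        grid[None, :, None], grid[None, None, :], w_A, w_B, p_H,
        (cpair(fa, "alpha"), cpair(fa, "gamma")),
        (cpair(ma, "alpha"), cpair(ma, "gamma")),
        (mu_F["alpha"], mu_F["gamma"]),
        (mu_M["alpha"], mu_M["gamma"]),
    )
    umax = util.max(axis=(1, 2), keepdims=True)
    tied = util >= umax - _TIE_EPS
    prev_A = state.alpha[:half][:, None, None]
    prev_B = state.alpha[half:][:, None, None]
    key = (np.abs(grid[None, :, None] - prev_A)
           + np.abs(grid[None, None, :] - prev_B)
           + 1e-7 * grid[None, :, None] + 1e-9 * grid[None, None, :])
    key = np.where(tied, key, np.inf)
    flat = key.reshape(H, -1).argmin(axis=1)
    i, j = np.unravel_index(flat, (grid.size, grid.size))
    alpha = np.concatenate([grid[i], grid[j]])
    uh = util.reshape(H, -1)[np.arange(H), flat]
    utility = np.concatenate([uh, uh])
    state.alpha = alpha
    state.n_household_steps += H
    return alpha, utility


def step(state: SimulationState, config: ModelConfig | None = None) -> SimulationState:
    """Execute one time step: decisions under frozen norms, then norm update.

    Every household (or individual) decides against the norm means computed
    at the end of the previous step, so processing order cannot matter; the
    new means are the plain averages of this step's behaviours.
    """
    config = config or state.config
    if config.model == "ihm":
        alpha, utility = _step_ihm(state)
    elif config.model == "im":
        alpha, utility = _step_im(state)
    else:
        alpha, utility = _step_um(state)

    t = state.step
    mu_used = {g: dict(ns.means) for g, ns in state.norms.items()}
    state.records.append({
        "t": t,
        "alpha": alpha.copy(),
        "theta": state.theta.copy(),
        "direction": state.direction.copy(),
        "utility": utility,
        "mu": mu_used,
    })

    # synchronous norm update from this step's behaviours
    half = state.n_households
    comps = _norm_components(config.model)
    theta_by_agent = np.concatenate([state.theta, state.theta])
    for gender, sl in ((Gender.FEMALE, slice(0, half)),
                       (Gender.MALE, slice(half, 2 * half))):
        behaviors = [
            {c: v for c, v in (("alpha", alpha[i]),
                               ("gamma", 1.0 - alpha[i]),
                               ("theta", theta_by_agent[i])) if c in comps}
            for i in range(sl.start, sl.stop)
        ]
        means = update_norms(behaviors)
        state.norms[gender] = dataclasses.replace(
            state.norms[gender], means=means
        )
    state.step = t + 1
    return state


def _records_to_frame(state: SimulationState) -> pd.DataFrame:
    cfg = state.config
    n = len(state.agents)
    half = n // 2
    agent_id = np.array([a.agent_id for a in state.agents])
    gender = np.array([a.gender.value for a in state.agents])
    household_id = np.array([f"h{i % half:03d}" for i in range(n)])
    frames = []
    for rec in state.records:
        mu = rec["mu"]
        dir_codes = np.concatenate([rec["direction"], rec["direction"]])
        theta = np.concatenate([rec["theta"], rec["theta"]])
        frames.append(pd.DataFrame({
            "model": cfg.model,
            "condition": cfg.condition,
            "seed": cfg.seed,
            "w_f_post": cfg.w_f_post,
            "t": rec["t"],
            "agent_id": agent_id,
            "household_id": household_id,
            "gender": gender,
            "alpha": rec["alpha"],
            "gamma": 1.0 - rec["alpha"],
            "theta": theta,
            "theta_direction": [
                _DIR_CODE[int(d)].value if th > 0 else Direction.NONE.value
                for d, th in zip(dir_codes, theta)
            ],
            "utility": rec["utility"],
            "norm_mu_alpha": np.array(
                [mu[Gender.FEMALE]["alpha"]] * half + [mu[Gender.MALE]["alpha"]] * half),
            "norm_mu_gamma": np.array(
                [mu[Gender.FEMALE]["gamma"]] * half + [mu[Gender.MALE]["gamma"]] * half),
            "norm_mu_theta": np.array(
                [mu[Gender.FEMALE].get("theta", 0.0)] * half
                + [mu[Gender.MALE].get("theta", 0.0)] * half),
        }))
    df = pd.concat(frames, ignore_index=True)
    return df


def prepare_prechange_state(
    config: ModelConfig,
    agents: list[AgentParams] | None = None,
    high_conformity: dict[str, dict[str, float]] | None = None,
) -> SimulationState:
    """Run steps 1 .. t_change-1 (the segment shared by all wage levels)."""
    state = init_population(config, agents, high_conformity)
    while state.step < config.t_change:
        step(state, config)
    return state


def continue_run(state: SimulationState, config: ModelConfig) -> pd.DataFrame:
    """Apply the change event and run to ``t_end``; return the tidy series."""
    if state.step == config.t_change and not state.change_applied:
        apply_change_event(state, config)
    while state.step <= config.t_end:
        step(state, config)
    df = _records_to_frame(state)
    # stabilization diagnostic: largest allocation move in the window just
    # before the change
    pre = [r for r in state.records
           if config.t_change - 5 <= r["t"] < config.t_change]
    drift = 0.0
    for r1, r2 in zip(pre, pre[1:]):
        drift = max(drift, float(np.max(np.abs(r2["alpha"] - r1["alpha"]))))
    df.attrs["max_prechange_drift"] = drift
    df.attrs["nonconverged_household_steps"] = state.n_nonconverged
    df.attrs["household_steps"] = state.n_household_steps
    df.attrs["log"] = list(state.log)
    return df


def run(
    config: ModelConfig,
    agents: list[AgentParams] | None = None,
    high_conformity: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Run one full simulation and return the tidy agent-step time series.

    One row per agent per step 1..t_end.  Deterministic given the config
    (the seed is the only source of randomness).  Run diagnostics are
    attached in ``df.attrs``.
    """
    state = prepare_prechange_state(config, agents, high_conformity)
    return continue_run(state, config)
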