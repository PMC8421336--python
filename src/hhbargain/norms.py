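"""Gender norm populations: conformity-weighted distance penalty and update.

A norm has a *population* (all agents of one gender) and a *protocol*: the
penalty an agent incurs is the conformity-weighted sum of squared distances
between its own behaviours and the population's mean behaviours from the
previous time step,

    N = sum_i c_i * (x_i - mu_i)^2 ,

entering utility multiplicatively as ``exp(-N)``.  In the full household
model the tracked components are time on the private activity (alpha), time
on the public activity (gamma) and the household transfer magnitude (theta);
the comparison models track only alpha and gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["NormState", "norm_distance", "norm_penalty", "update_norms"]

_VALID_COMPONENT_SETS = (
    frozenset({"alpha", "gamma", "theta"}),
    frozenset({"alpha", "gamma"}),
)


@dataclass
class NormState:
    """Mean behaviours of one norm population (one per gender).

    ``means`` maps component name to the population mean, each in [0, 1].
    """

    population_id: str
    means: Mapping[str, float]
    membership: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        comps = frozenset(self.means)
        if comps not in _VALID_COMPONENT_SETS:
            raise ValueError(
                "norm components must be {alpha, gamma, theta} or {alpha, gamma}; "
                f"got {sorted(comps)}"
            )
        for k, v in self.means.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"norm mean {k}={v} outside [0, 1]")


def norm_distance(x: float, mu: float) -> float:
    """Squared distance from the population mean, ``(x - mu)**2``."""
    return (x - mu) ** 2


def norm_penalty(
    behaviors: Mapping[str, float],
    norm: NormState,
    conformity: Mapping[str, float],
) -> tuple[float, float]:
    """Conformity-weighted penalty and its multiplicative utility factor.

    Returns ``(N, exp(-N))`` with ``N = sum_i c_i * (x_i - mu_i)^2`` over the
    supplied behaviour components.  Components must be a subset of the
    norm's tracked components.
    """
    extra = set(behaviors) - set(norm.means)
    if extra:
        raise ValueError(f"behaviours {sorted(extra)} not tracked by norm "
                         f"{norm.population_id}")
    n = 0.0
    for comp, x in behaviors.items():
        c = conformity.get(comp, 0.0)
        n += c * norm_distance(x, norm.means[comp])
    return n, math.exp(-n)


def update_norms(
    population_behaviors: Iterable[Mapping[str, float]],
) -> dict[str, float]:
    """Arithmetic mean of each behaviour component over the population.

    Called once per gender population at the end of a time step; the result
    becomes the norm means every member uses at the next step.
    """
    rows = list(population_behaviors)
    if not rows:
        raise ValueError("cannot update a norm from an empty population")
    comps = set(rows[0])
    sums = {c: 0.0 for c in comps}
    for row in rows:
        if set(row) != comps:
            raise ValueError("inconsistent behaviour components across members")
        for c in comps:
            sums[c] += row[c]
    return {c: s / len(rows) for c, s in sums.items()}
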