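# Methods

## Model overview

`hhbargain` simulates populations of two-member households whose members
divide unit time budgets between a private activity (wage work, output
`w·α`, individually consumed, transferable) and a public activity (output
`γ_A + γ_B`, consumed by both). Member utility is a preference-weighted sum
of square-rooted goods — the square roots give diminishing returns, which
keeps agents from oscillating between corner behaviours — multiplied by a
social-norm factor `e^(−N)` with `N = Σ_i c_i (x_i − μ_i)²`: the
conformity-weighted squared distance between the agent's behaviours and its
gender population's mean behaviours. Three decision models share this
machinery:

- **IHM** (intra-household): members bargain. For each candidate transfer
  θ on a grid (both directions), the members alternate best responses over
  their own time allocation, A first, until the pair of allocations repeats
  — the agreement at that θ. Among agreements where both members do at
  least as well as at the θ = 0 agreement (the separate-spheres threat
  point), the household adopts the one maximizing the Nash product of
  utility gains. The IHM norm tracks α, γ and the household's θ magnitude.
- **IM** (individual): each agent maximizes
  `p_α √(wα) + p_γ √(1−α)` times its norm factor; no coupling between
  spouses. Norms track α and γ only.
- **UM** (unitary): one household utility with pooled private earnings and
  the members' norm penalties summed; the household preference weight is
  the mean of the members' weights (a `head_male` alternative adopts the
  male member's weights; the mean is the default because it keeps sampled
  attributes comparable across models). Norms track α and γ only.

The norm penalty applies inside *every* utility evaluation — candidate
allocations during best responses, threat points, and the Nash objective —
since the utility definition carries the factor unconditionally.

### Transfer semantics

θ is stored as a magnitude plus a direction; utilities use the signed form
(positive = A→B). The transferor loses the fraction θ of its own private
output; the transferee gains that amount inside its square root, so the
transfer conserves goods. The direction is not imposed: both directions are
searched and the Nash product arbitrates. In the experiments the selected
direction is overwhelmingly husband→wife, which is the economically
sensible outcome given the wage gap.

## Solver

Allocations live on a grid of step 0.01 over [0, 1] (`alpha_grid_step`),
transfers on a grid of step 0.05 (`theta_grid_step`), searched in both
directions (41 signed values). Best-response argmaxes break utility ties
(within 1e−12) toward the agent's current allocation, then the smaller α —
behavioural inertia that makes flat objective regions deterministic.
Bargain selection breaks Nash-product ties toward the smaller |θ|, then
the previous step's direction. The alternation is capped at 100 rounds
(`max_iterations`); non-repeating iterations are logged, the last iterate
used (at full scale this affects ~1 in 10⁴ household-θ cells). The
participation constraints carry a 1e−9 slack (`constraint_tol`).

One set of numpy kernels broadcasts over arbitrary leading axes, so the
engine solves all 100 households × 41 transfer levels simultaneously per
step, warm-starting from the previous step's per-θ agreements; the
per-household API (`select_bargain`, `threat_point`, …) wraps the same
kernels, and tests assert the two paths agree exactly. A separate
exhaustive oracle (`brute_force_bargain`) scores every joint
(α_A, α_B, signed θ) grid point directly with the scalar reference utility
and is used in tests only (guarded against grids beyond 51×51×41 points).

### Grid discreteness

Two consequences of the discrete grid are worth knowing. First, the A-first
alternation can settle with exactly symmetric members one cell apart
(mutual best responses in adjacent cells), so symmetry holds to grid
resolution, not exactly. Second, the two-step protocol only ever agrees on
alternating-best-response equilibria; free joint optimization (the
exhaustive oracle) can find non-equilibrium allocation pairs with higher
Nash products — coordination gains the bargaining protocol cannot reach.
The oracle is therefore an upper bound on the solver's objective (asserted
in tests), not an equality.

## Simulation schedule

Agents are sampled once per run from a seeded generator: private-good
preference `p_α ~ U(0.3, 0.7)` (with `p_γ = 1 − p_α`), each conformity
component `~ U(0.3, 0.7)`, and a second set of high conformity components
`~ U(2.5, 3.0)` drawn for every agent in the same pass. Drawing both sets
for everyone keeps populations bit-identical across models, conditions and
wage levels for a given seed; the high values are only *applied* where the
scenario calls for them. The first half of the population is female,
household *h* pairs female *h* with male *h* (the pairing rule is
arbitrary and seed-stable), and the dynamics consume no randomness, so runs
are exactly reproducible.

Initial allocations encode the traditional gender roles: males at
α = 0.8, females at α = 0.2, transfers at zero; norm means start at the
population means of those values. Decisions at step *t* use the norm means
computed from behaviours at the end of step *t − 1* (synchronous update),
so household processing order cannot matter within a step.

At `t_change` (default 25, by which point the populations have settled —
the engine reports the largest allocation move over the five preceding
steps as a diagnostic) the female wage jumps from 0.1 to `w_f_post`, before
the decisions of that step. Under the **CM** condition male agents'
conformity components are simultaneously replaced by their pre-drawn high
values (for the UM, both members' — the unitary household is the
conformist unit there; for the IM, male individuals). Under **MP** nothing
but the wage changes. Runs end at `t_end = 150`.

The wage sweep repeats this for twelve post-change wages
{0.15, 0.2, 0.25, 0.3, 0.4, …, 1.0, 1.1}, sharing the seed; the pre-change
segment is computed once and the state copied per wage level, which is
bit-identical to independent runs (tested). Behaviour change is
`α(150) − α(26)` per agent; t = 26 is the step after the first post-change
decision.

## What the generator emulates — and what it does not

The synthetic populations reproduce the study conditions exactly: uniform
preference/conformity heterogeneity, a 6× initial gender wage gap, gendered
starting roles, and a one-shot wage intervention. They do *not* emulate
real survey households: there are no children, no asset dynamics, no
heterogeneity in household size, no correlation between spouses'
preferences, and the norm populations are closed. Passing tests therefore
show that the three decision architectures produce their characteristic
comparative dynamics under controlled conditions — not that any of them is
calibrated to an empirical population.

## Analytics

- `behavior_change`: per-agent `α(t_to) − α(t_from)` from the tidy series.
- `pearson_r` / `compare_groups`: standard Pearson correlation and Welch's
  unequal-variance t test (scipy), used for the near-linearity of the IM
  female response and the low-wage contrast.
- `transition_threshold`: the largest grid wage whose mean |Δα| stays
  below 5% (configurable) of the grid maximum — an operationalization of a
  "sudden" workforce transition. It is designed for the UM's step-shaped
  response; for the IHM under CM the low-wage *negative* anomaly dominates
  the |Δα| curve and the rule misfires, so cross-condition comparisons of
  female entry use the first wage with mean Δα ≥ 0.05 instead (reported
  alongside the raw curves).

## Numerical choices and degenerate inputs

Radicands are clipped at zero (they are non-negative by construction;
clipping guards float rounding). Zero-preference corners (p_α ∈ {0, 1})
are permitted and resolve to the corresponding corner allocations, though
the experiments never sample them. Zero-variance inputs to the statistics
raise rather than returning NaN. Empty norm populations raise. The wage
must be positive; α is validated to [0, 1].

## Known limitations

Two-member households only; one resource (time) and two activities; linear
private and additive public production (the activity functions sit behind a
function interface, so richer activities can be plugged in); no re-pairing,
birth/death, or dynamic norm membership; a single pseudo-random stream
consumed only at parameter sampling. The alternation order (A = female
first) is fixed; its only observable effect is the one-grid-cell asymmetry
noted above.
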