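# Methods

## The model class

`boolpop` simulates Boolean networks under continuous-time Markov chain
(CTMC) semantics. Each node holds a binary state; a node whose logic rule
disagrees with its state is enabled to flip — upward at its activation rate
`k_up` (per hour) when inactive, downward at its inactivation rate `k_down`
when active. A joint state with no enabled flip is absorbing. Trajectories
are simulated with the Gillespie algorithm: exponential waiting times at
the total enabled rate, the flipped node drawn proportionally to its rate.
Node activities are reported as *windowed, time-averaged* activation
probabilities estimated over a trajectory ensemble.

The population layer represents a growing or shrinking cell population on
top of the CTMC. Two designated utility nodes, Division and Death, act on
the trajectory ensemble in synchronous steps of width `step_dt`: at the end
of each step the probability mass of trajectories with Death active is set
to zero, the mass of trajectories with Division active is doubled and their
Division bit reset (daughters inherit the mother's other node states), and
the population ratio `pop_ratio` (size relative to t=0) is multiplied by
the resulting growth factor — `1 + P(division) − P(death)` when the two
events are disjoint. The distribution is then renormalized and "external"
rate parameters are recomputed from the end-of-step node marginals (cell
communication: a receptor's activation rate is proportional to the
probability that its ligand is present). The size of a cell population
readout is the cell node's marginal multiplied by `pop_ratio` at the same
time point.

A state carrying both Division and Death is resolved by the
`death_precedence` flag (default true: the state dies). This convention is
configurable because nothing in the update semantics forces either choice;
the default is the conservative one.

## Randomness and reproducibility

The ensemble kernel is vectorized across trajectories and consumes one
dedicated stream per reporting window, derived as
`SeedSequence([master_seed, window_index])`; initial states use a separate
fixed salt. Because exponential waiting times are memoryless, restarting
the clock at window boundaries leaves the process law unchanged, and the
protocol has two useful consequences:

* a population run whose population layer is trivial (no Division/Death,
  no update rules) is *bitwise identical* to a plain ensemble run with the
  same master seed; and
* a run resumed from a checkpoint (the chained perturbation protocol)
  reuses the same per-step streams as the uninterrupted run, so the
  untreated and treated arms share their random numbers — identical before
  the switch, common-random-number coupled after it.

The scalar `simulate_trajectory` API instead derives one stream per
trajectory, which is the natural contract for jump-level work
(reproducible individual jump sequences).

When Division/Death reweighting makes trajectory weights uneven, the
ensemble is systematically resampled once the effective sample size falls
below half the nominal size. Resampling never triggers while weights are
uniform, preserving the exactness of the plain-ensemble limit.

## Chained perturbation protocol

Treatments are simulated as chained runs: the disease trigger is applied
at t=0, the untreated arm runs to the horizon, and the treated arm resumes
from the untreated population state at the switch time (default 300 h)
with the perturbation applied — node clamps (inhibition = fixed at 0,
activation = fixed at 1) and/or rate-parameter multipliers (e.g. a
co-inhibitory mechanism modelled as a faster downregulation rate) — and
continues to the evaluation time (default 600 h). Note that under CTMC
semantics an inactivation rate only matters for nodes whose rule is
sometimes false; multiplier perturbations should target such parameters.

Per readout the response is `100·(P_treated − P_untreated)/P_untreated`
evaluated at the final window; it is undefined (NaN) for a zero untreated
baseline. Because the literature is ambiguous about whether cell readouts
are compared on activation probability or population size, the response
table always carries both (`response_marginal_pct`,
`response_population_pct`). Screens share one untreated arm across all
candidates and can optionally collapse a receptor candidate onto its
unique ligand, since clamping either member of a ligand→receptor copy pair
has near-identical downstream effects.

## Sensitivity scan

One-at-a-time: every rate parameter is scaled by (1−f) and (1+f) with
f = 0.5 by default, each variant is re-simulated, and per node the
deviation from the wild-type marginal over the first 200 h (the span
within which the models studied here reach their asymptotic regime) is
summarized as the maximum windowed absolute difference — the conservative
aggregation; the mean is reported alongside. Deviations at or above the
threshold (default 0.1) are flagged. Wild type and variants share the
master seed by default so common Monte-Carlo noise cancels; independent
seeding is available and then the deviation includes sampling noise.

## Network control

The influence graph has one signed edge per (regulator, target, polarity)
triple, read syntactically off the rules (odd NOT-nesting → inhibiting);
a regulator appearing under both polarities yields two opposite-signed
edges rather than a hidden ambiguity. Division, Death and the trigger are
excluded from control analysis — they are population-layer plumbing, not
disease circuitry.

Feedback vertex sets of size two are enumerated among the
cycle-participating nodes (members of nontrivial strongly connected
components plus self-loop nodes) by testing whether joint removal leaves
the graph acyclic. Candidate pairs are ranked by three propagation
measures:

* **PRINCE**: fixed point of `F ← αW′F + (1−α)Y` on the underlying
  undirected graph, `W′ = D^{−1/2} A D^{−1/2}`, `Y` the pair indicator;
  the pair's score is the total smoothed mass.
* **Modified PRINCE**: the same iteration on the directed graph with
  out-degree normalization and edge signs as weights; scores can be
  negative through inhibiting edges, so the pair aggregates magnitudes.
* **CheiRank**: PageRank on the edge-reversed simple graph (damping 0.85),
  scoring outgoing influence; the pair sums its members' scores.

Defaults α = 0.85, damping = 0.85, fixed-point tolerance 1e−9 and an
intersection `top_fraction` of 0.2 are package choices, all configurable.
The final rank orders pairs inside the top fraction of *all three* metrics
(the intersection) by their mean dense rank, then the remaining pairs the
same way; ties break lexicographically. Druggability follows the node
class — ligands, receptors and transcription factors are druggable, cell
and cell-state nodes are not — and the druggable filter reports both
counting conventions (pairs containing ≥1 non-druggable member, and pairs
with both members druggable) for audit.

## Synthetic models

The generator family serves three roles. Analytic cases pin the engine to
independent mathematics: a constant-true node activates as
`P(t) = 1 − e^{−kt}`; a pure-division population grows as `e^{dT}` in the
small-step limit; a pure-death population decays as `e^{−mT}`; small
networks are integrated exactly through the 2^n-state master equation
(scipy LSODA, trapezoid quadrature for window averages). The toy
multiscale model reproduces the architecture of the psoriasis-style
disease models this toolkit targets — persistent trigger, activated-cell
layer, ligand→receptor→transcription-factor chains, a proliferating cell
state wired to Division/Death, optional cross-layer feedback closing a
self-sustaining loop, and receptor rates recomputed each step from ligand
marginals. Rates are drawn log-uniform within class-typical ranges
(ligands decay fast, per the convention that extracellular cytokine
signals are rapidly depleted); toy models stay at ≤ 20 nodes so the
master-equation oracle remains feasible. Random signed digraphs
(Erdős–Rényi) back the exhaustive FVS comparisons.

What the synthetic models do *not* emulate: real rule curation (the toys
are copy chains and single gates, not literature-derived logic), spatial
effects, immune-cell proliferation, or realistic parameter magnitudes
beyond class conventions. Passing tests therefore demonstrate the
correctness of the simulation and analysis machinery, not the biological
fidelity of any particular disease model.

## Numerical and statistical choices

* Problem sizes: validation ensembles use 20,000–100,000 trajectories
  depending on the precision the comparison needs (the default production
  ensemble is 50,000); the birth-process check uses 100,000 so that the
  Monte-Carlo noise (SD ≈ 0.7%) is small against its 5% band, which also
  absorbs the ≈ −2.4% discretization bias of the synchronous step at
  `step_dt = 0.1` (the growth factor compounds `1 + P(div)` rather than
  `e^{d·dt}`).
* Monte-Carlo comparisons use binomial standard errors; per-trajectory
  window occupancies lie in [0, 1], so `p(1−p)/n` bounds the estimator
  variance. Whole-timecourse comparisons correct for multiplicity
  (Bonferroni over cells) so the family-wise false-alarm rate matches a
  single 3σ test.
* Master-equation integration: LSODA at rtol 1e−9/atol 1e−12, dense
  output, 16-point trapezoid per window; networks capped at 12 nodes
  (4096 states dense).
* Zero total rate is an absorbing state, not a division by zero; clamped
  nodes are excluded from the rate sum from the start.
* Rule tables are precomputed per node over its inputs (capped at 16
  inputs), making rule evaluation a vectorized table lookup.
* Extinction (total mass zero after a death update) terminates the run
  and is flagged on the timecourse rather than raising mid-simulation;
  resuming a chained run past an extinct switch point is an error.

## Known limitations

* The exact solver is dense and limited to small networks; it is a
  validation oracle, not a production path.
* The population layer tracks one global `pop_ratio`; models where several
  cell types divide independently need per-type Division wiring within one
  shared ratio, as in the keratinocyte-only convention used here.
* Sign-aware propagation aggregates magnitudes; cancellation between
  activating and inhibiting paths is therefore visible in the node scores
  but not in the pair totals.
* No variance reduction beyond common random numbers and resampling;
  deep-tail probabilities need larger ensembles.
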