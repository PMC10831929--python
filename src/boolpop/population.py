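"""The population layer: synchronous Division/Death reweighting on top of
the CTMC engine, population-ratio tracking and ligand-coupled rate updates.

Each population step simulates the trajectory ensemble for ``step_dt``
hours with the current rates, then synchronously:

1. zeroes the probability mass of trajectories whose Death node is active,
2. doubles the mass of trajectories whose Division node is active and
   resets their Division bit (daughters inherit the mother's other states),
3. multiplies the population ratio by the resulting growth factor
   (``1 + P(division) - P(death)`` when the two events are disjoint),
4. renormalizes the mass, and
5. recomputes the listed "external" rate parameters from the end-of-step
   node marginals and the population ratio (cell communication: the more
   of a ligand is present, the faster its receptor activates).

The size of a cell population readout is the product of the cell node's
activation probability and the population ratio at the same time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import expr
from .engine import (
    CompiledModel,
    MarginalTimecourse,
    advance_ensemble,
    init_rng,
    sample_initial_states,
    window_rng,
)
from .model import BooleanNetwork, ModelError, PopulationConfig, SimulationConfig

__all__ = [
    "PopulationExtinct",
    "StepDistribution",
    "PopulationState",
    "PopulationTimecourse",
    "apply_division_death",
    "update_external_rates",
    "run_population",
    "simulate",
]


class PopulationExtinct(RuntimeError):
    """Raised when the entire probability mass dies in one step."""


@dataclass
class StepDistribution:
    """A weighted collection of joint states (probability mass)."""

    states: np.ndarray  # (m, n) uint8
    weights: np.ndarray  # (m,) nonnegative, summing to 1

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.uint8)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.states.ndim != 2 or self.weights.shape != (self.states.shape[0],):
            raise ValueError("states must be (m, n) with matching weights (m,)")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    def normalized(self) -> "StepDistribution":
        total = self.weights.sum()
        if total <= 0:
            raise PopulationExtinct("total probability mass is zero")
        return StepDistribution(self.states, self.weights / total)

    def marginals(self) -> np.ndarray:
        total = self.weights.sum()
        return (self.weights @ self.states) / total if total > 0 else np.zeros(self.states.shape[1])


def apply_division_death(
    dist: StepDistribution,
    division_idx: int | None,
    death_idx: int | None,
    death_precedence: bool = True,
) -> tuple[StepDistribution, float]:
    """Division/Death reweighting of an end-of-step distribution.

    States with the Death node active lose their mass; states with the
    Division node active have their mass doubled and the Division bit reset
    (the doubled mass represents mother plus daughter, both starting from
    the mother's state).  ``death_precedence`` decides the fate of states
    carrying both bits: death wins when True (default), division when
    False.

    Returns the renormalized distribution and the growth factor (total
    post-adjustment mass over total input mass; 1 + P(div) - P(death) when
    the two sets are disjoint).  A growth factor of 0 means extinction; the
    returned distribution is then the (unnormalizable) zero-mass input and
    callers should treat the population as terminated.
    """
    m, n = dist.states.shape
    w = dist.weights.copy()
    div = dist.states[:, division_idx] == 1 if division_idx is not None else np.zeros(m, bool)
    dth = dist.states[:, death_idx] == 1 if death_idx is not None else np.zeros(m, bool)
    if death_precedence:
        w[dth] = 0.0
        w[div & ~dth] *= 2.0
    else:
        w[div] *= 2.0
        w[dth & ~div] = 0.0
    total_in = dist.weights.sum()
    total_out = w.sum()
    growth = total_out / total_in if total_in > 0 else 0.0
    states = dist.states
    if division_idx is not None and div.any():
        states = states.copy()
        states[div, division_idx] = 0
    if total_out > 0:
        w = w / total_out
    return StepDistribution(states, w), growth


def update_external_rates(
    parameters: dict[str, float],
    marginals: dict[str, float],
    pop_ratio: float,
    update_rules: list[tuple[str, tuple]],
) -> dict[str, float]:
    """Recompute the listed parameters from end-of-step node marginals.

    All other parameters are untouched.  New values must be nonnegative
    and finite (rates).
    """
    out = dict(parameters)
    for param, ast in update_rules:
        v = expr.arith_eval(ast, parameters, probs=marginals, pop_ratio=pop_ratio)
        if not np.isfinite(v) or v < 0:
            raise ModelError(f"update rule for ${param} produced invalid rate {v}")
        out[param] = v
    return out


# --------------------------------------------------------------------------
# results and checkpoints
# --------------------------------------------------------------------------


@dataclass
class PopulationState:
    """Checkpoint of a population run, sufficient to resume it."""

    states: np.ndarray
    weights: np.ndarray
    pop_ratio: float
    parameters: dict[str, float]
    step_index: int  # number of steps already taken


@dataclass
class PopulationTimecourse:
    """Per-step marginals, end-of-step marginals and population ratio.

    ``marginals[s]`` is the time-averaged activation probability within
    step ``s`` (the reporting window ``[s*dt, (s+1)*dt)``);
    ``pop_ratio[s]`` is the population size relative to t=0 after ``s``
    steps (``pop_ratio[0] == 1``).
    """

    node_names: list[str]
    step_dt: float
    marginals: np.ndarray  # (n_steps, n_nodes) window-averaged
    end_marginals: np.ndarray  # (n_steps, n_nodes) instantaneous, post-update
    pop_ratio: np.ndarray  # (n_steps + 1,)
    n_trajectories: int = 0
    extinct_at_step: int | None = None

    @property
    def n_steps(self) -> int:
        return self.marginals.shape[0]

    @property
    def times(self) -> np.ndarray:
        """End time of each step."""
        return (np.arange(self.n_steps) + 1) * self.step_dt

    def marginal(self, node: str) -> np.ndarray:
        return self.marginals[:, self.node_names.index(node)]

    def population_size(self, node: str) -> np.ndarray:
        """Cell-population size: marginal × pop_ratio, per step."""
        return self.marginal(node) * self.pop_ratio[1:]

    def final_marginal(self, node: str) -> float:
        return float(self.marginals[-1, self.node_names.index(node)])

    def final_size(self, node: str) -> float:
        return float(self.population_size(node)[-1])

    def as_timecourse(self) -> MarginalTimecourse:
        return MarginalTimecourse(
            node_names=list(self.node_names),
            window_dt=self.step_dt,
            probs=self.marginals,
            n_trajectories=self.n_trajectories,
        )

    def to_frame(self, cell_nodes: list[str] | None = None) -> pd.DataFrame:
        """Wide format: step, time, pop_ratio, one column per node marginal,
        plus one ``size:<node>`` column per listed cell node."""
        df = pd.DataFrame(self.marginals, columns=self.node_names)
        df.insert(0, "pop_ratio", self.pop_ratio[1:])
        df.insert(0, "time", self.times)
        df.insert(0, "step", np.arange(self.n_steps))
        for node in cell_nodes or []:
            df[f"size:{node}"] = self.population_size(node)
        return df

    def concat(self, other: "PopulationTimecourse") -> "PopulationTimecourse":
        if other.node_names != self.node_names or other.step_dt != self.step_dt:
            raise ValueError("cannot concatenate incompatible timecourses")
        return PopulationTimecourse(
            node_names=list(self.node_names),
            step_dt=self.step_dt,
            marginals=np.vstack([self.marginals, other.marginals]),
            end_marginals=np.vstack([self.end_marginals, other.end_marginals]),
            pop_ratio=np.concatenate([self.pop_ratio, other.pop_ratio[1:]]),
            n_trajectories=self.n_trajectories,
            extinct_at_step=other.extinct_at_step,
        )


def _resample(states, weights, rng):
    """Systematic resampling back to uniform weights."""
    N = len(weights)
    positions = (rng.random() + np.arange(N)) / N
    cum = np.cumsum(weights)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, positions)
    return states[idx].copy(), np.full(N, 1.0 / N)


def run_population(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    popcfg: PopulationConfig,
    seed: int | None = None,
    start: PopulationState | None = None,
    n_steps: int | None = None,
    capture_step: int | None = None,
) -> tuple[PopulationTimecourse, PopulationState | None]:
    """Run the synchronous population loop.

    ``start`` resumes from a checkpoint (chained simulations); randomness
    for step ``s`` comes from a stream derived from ``(seed, global step
    index)``, so a resumed run that changes nothing reproduces the original
    continuation and a perturbed resume shares its random numbers with the
    unperturbed arm (common random numbers).

    Returns the timecourse and, if ``capture_step`` is given, the
    checkpoint taken after that many steps.
    """
    cfg.validate(net)
    popcfg.validate(net, cfg)
    master = cfg.seed if seed is None else seed
    steps = popcfg.n_steps if n_steps is None else n_steps
    offset = start.step_index if start is not None else 0

    params = dict(start.parameters) if start is not None else dict(cfg.parameters)
    model = CompiledModel(net, params)
    if start is not None:
        states = start.states.copy()
        weights = start.weights.copy()
        model.apply_clamps(states)
        pop_ratio = start.pop_ratio
        N = states.shape[0]
    else:
        N = cfg.n_trajectories
        states = sample_initial_states(model, cfg.istate, N, init_rng(master))
        weights = np.full(N, 1.0 / N)
        pop_ratio = 1.0

    div_idx = model.index[popcfg.division_node] if popcfg.division_node else None
    death_idx = model.index[popcfg.death_node] if popcfg.death_node else None

    marg = np.zeros((steps, model.n))
    end_marg = np.zeros((steps, model.n))
    ratios = np.empty(steps + 1)
    ratios[0] = pop_ratio
    captured: PopulationState | None = None
    extinct_at: int | None = None
    if capture_step == 0:
        captured = PopulationState(states.copy(), weights.copy(), pop_ratio, dict(params), offset)

    for s in range(steps):
        rng = window_rng(master, offset + s)
        occ = advance_ensemble(model, states, weights, popcfg.step_dt, rng)
        marg[s] = occ / (popcfg.step_dt * weights.sum())

        if div_idx is not None or death_idx is not None:
            dist = StepDistribution(states, weights)
            dist, growth = apply_division_death(
                dist, div_idx, death_idx, popcfg.death_precedence
            )
            if growth <= 0.0:
                extinct_at = s
                ratios[s + 1 :] = 0.0
                marg[s + 1 :] = np.nan
                end_marg[s:] = np.nan
                break
            states, weights = dist.states, dist.weights
            pop_ratio *= growth
        ratios[s + 1] = pop_ratio
        end_marg[s] = weights @ states

        if popcfg.update_rules:
            probs = dict(zip(model.names, end_marg[s]))
            params = update_external_rates(params, probs, pop_ratio, popcfg.update_rules)
            model.set_parameters(params)

        # keep the weighted ensemble healthy on long runs; never triggers
        # while weights are uniform (plain-ensemble limit stays exact)
        ess = 1.0 / np.square(weights).sum()
        if ess < popcfg.resample_ess * N and not np.allclose(weights, weights[0]):
            states, weights = _resample(states, weights, rng)

        if capture_step is not None and s + 1 == capture_step:
            captured = PopulationState(
                states.copy(), weights.copy(), pop_ratio, dict(params), offset + s + 1
            )

    tc = PopulationTimecourse(
        node_names=list(model.names),
        step_dt=popcfg.step_dt,
        marginals=marg,
        end_marginals=end_marg,
        pop_ratio=ratios,
        n_trajectories=N,
        extinct_at_step=extinct_at,
    )
    return tc, captured


def simulate(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    popcfg: PopulationConfig | None = None,
    seed: int | None = None,
) -> PopulationTimecourse:
    """One-call simulation entry point.

    Without a population config this is a plain ensemble run presented in
    the same container (pop_ratio identically 1).
    """
    if popcfg is None:
        popcfg = PopulationConfig(
            n_steps=cfg.n_windows, step_dt=cfg.window_dt, division_node=None, death_node=None
        )
    tc, _ = run_population(net, cfg, popcfg, seed=seed)
    return tc
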