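"""Continuous-time Markov chain simulation of Boolean networks.

Semantics: each node whose rule value disagrees with its current state is
enabled to flip — upward at its activation rate ``k_up`` when inactive,
downward at its inactivation rate ``k_down`` when active.  Trajectories
follow the Gillespie scheme: exponential waiting times at the total enabled
rate, the flipped node chosen proportionally to its rate.  A state where no
flip is enabled is absorbing.  Clamped nodes never transition.

Node marginals are reported as time-averaged occupancies within fixed
reporting windows, estimated over a (possibly weighted) trajectory
ensemble.  The ensemble kernel is vectorized across trajectories and draws
its randomness from one stream per reporting window derived from the master
seed (``SeedSequence([seed, window_index])``); because exponential waiting
times are memoryless, restarting the clock at window boundaries leaves the
process law unchanged while making windowed runs exactly composable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import expr
from .model import BooleanNetwork, ModelError, SimulationConfig

__all__ = [
    "CompiledModel",
    "MarginalTimecourse",
    "Trajectory",
    "enabled_transitions",
    "simulate_trajectory",
    "estimate_marginals",
    "ensemble_marginals",
    "advance_ensemble",
    "sample_initial_states",
]

_MAX_RULE_INPUTS = 16

# fixed salt for the initial-state stream, distinct from any window index
_INIT_STREAM = 0x5EED_1111


class CompiledModel:
    """A network compiled for fast vectorized simulation.

    Rules are lowered to per-node truth tables over their input nodes;
    rate expressions are evaluated against the current parameter values
    into dense ``k_up``/``k_down`` arrays (refreshed by
    :meth:`set_parameters` when the population layer updates them).
    """

    def __init__(self, net: BooleanNetwork, parameters: dict[str, float]):
        self.net = net
        self.names = net.names
        self.index = {n: i for i, n in enumerate(self.names)}
        self.n = len(self.names)

        self._inputs: list[np.ndarray] = []
        self._tables: list[np.ndarray] = []
        for decl in net.nodes:
            inputs = decl.inputs
            if len(inputs) > _MAX_RULE_INPUTS:
                raise ModelError(
                    f"rule of {decl.name!r} has {len(inputs)} inputs "
                    f"(limit {_MAX_RULE_INPUTS})"
                )
            idx = np.array([self.index[x] for x in inputs], dtype=np.intp)
            table = np.empty(1 << len(inputs), dtype=np.uint8)
            for m in range(table.size):
                env = {name: (m >> j) & 1 for j, name in enumerate(inputs)}
                table[m] = expr.bool_eval(decl.logic, env)
            self._inputs.append(idx)
            self._tables.append(table)

        self.clamp_idx = np.array(
            [self.index[k] for k in net.clamps], dtype=np.intp
        )
        self.clamp_val = np.array(
            [net.clamps[k] for k in net.clamps], dtype=np.uint8
        )
        self.parameters: dict[str, float] = {}
        self.k_up = np.zeros(self.n)
        self.k_down = np.zeros(self.n)
        self.set_parameters(parameters)

    def set_parameters(self, parameters: dict[str, float]) -> None:
        self.parameters = dict(parameters)
        for i, decl in enumerate(self.net.nodes):
            up = expr.arith_eval(decl.rate_up, self.parameters)
            down = expr.arith_eval(decl.rate_down, self.parameters)
            if up < 0 or down < 0 or not np.isfinite(up) or not np.isfinite(down):
                raise ModelError(
                    f"rates of {decl.name!r} evaluate to ({up}, {down}); "
                    "must be finite and nonnegative"
                )
            self.k_up[i] = up
            self.k_down[i] = down

    # -- state handling ---------------------------------------------------

    def apply_clamps(self, states: np.ndarray) -> None:
        if self.clamp_idx.size:
            states[:, self.clamp_idx] = self.clamp_val

    def rule_values(self, states: np.ndarray) -> np.ndarray:
        """Rule value B_i(s) for every trajectory/node; shape like states."""
        out = np.empty_like(states)
        for i in range(self.n):
            idx = self._inputs[i]
            if idx.size == 0:
                out[:, i] = self._tables[i][0]
            else:
                packed = np.zeros(states.shape[0], dtype=np.intp)
                for j, col in enumerate(idx):
                    packed |= states[:, col].astype(np.intp) << j
                out[:, i] = self._tables[i][packed]
        return out

    def transition_rates(self, states: np.ndarray) -> np.ndarray:
        """Per-trajectory, per-node enabled flip rates (0 where disabled)."""
        bv = self.rule_values(states)
        enabled = bv != states
        rates = np.where(states == 1, self.k_down, self.k_up)
        rates = np.where(enabled, rates, 0.0)
        if self.clamp_idx.size:
            rates[:, self.clamp_idx] = 0.0
        return rates


def sample_initial_states(
    model: CompiledModel, istate: dict[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` initial joint states from independent node marginals."""
    states = np.zeros((n, model.n), dtype=np.uint8)
    for name, p in istate.items():
        i = model.index[name]
        if p >= 1.0:
            states[:, i] = 1
        elif p > 0.0:
            states[:, i] = rng.random(n) < p
    model.apply_clamps(states)
    return states


def advance_ensemble(
    model: CompiledModel,
    states: np.ndarray,
    weights: np.ndarray,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance every trajectory by ``duration``, in place.

    Returns the weighted occupancy time per node (shape ``(n,)``): the sum
    over trajectories of ``weight * time_spent_active`` within the window.
    Dividing by ``duration * weights.sum()`` gives the time-averaged
    marginal.
    """
    N = states.shape[0]
    occ = np.zeros(model.n)
    t = np.zeros(N)
    alive = np.ones(N, dtype=bool)
    fstates = states  # flips happen in place

    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        sub = fstates[idx]
        rates = model.transition_rates(sub)
        total = rates.sum(axis=1)

        absorbed = total <= 0.0
        if absorbed.any():
            ai = idx[absorbed]
            seg = duration - t[ai]
            occ += (weights[ai, None] * seg[:, None] * fstates[ai]).sum(axis=0)
            t[ai] = duration
            alive[ai] = False

        live = ~absorbed
        if not live.any():
            continue
        li = idx[live]
        ltot = total[live]
        dt = rng.exponential(1.0 / ltot)
        t_new = t[li] + dt

        over = t_new > duration
        if over.any():
            oi = li[over]
            seg = duration - t[oi]
            occ += (weights[oi, None] * seg[:, None] * fstates[oi]).sum(axis=0)
            t[oi] = duration
            alive[oi] = False

        jump = ~over
        if jump.any():
            ji = li[jump]
            seg = dt[jump]
            occ += (weights[ji, None] * seg[:, None] * fstates[ji]).sum(axis=0)
            cum = np.cumsum(rates[live][jump], axis=1)
            r = rng.random(ji.size) * ltot[jump]
            chosen = (cum < r[:, None]).sum(axis=1)
            chosen = np.minimum(chosen, model.n - 1)
            fstates[ji, chosen] ^= 1
            t[ji] = t_new[jump]
    return occ


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------


@dataclass
class MarginalTimecourse:
    """Windowed, time-averaged node-activation probabilities."""

    node_names: list[str]
    window_dt: float
    probs: np.ndarray  # shape (n_windows, n_nodes)
    n_trajectories: int = 0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(self.node_names):
            raise ValueError("probs must be (n_windows, n_nodes)")
        self.probs = p

    @property
    def n_windows(self) -> int:
        return self.probs.shape[0]

    @property
    def t_max(self) -> float:
        return self.n_windows * self.window_dt

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.window_dt

    def marginal(self, node: str) -> np.ndarray:
        return self.probs[:, self.node_names.index(node)]

    def at_time(self, t: float, node: str | None = None):
        """Value(s) in the window containing time ``t``."""
        w = min(int(t / self.window_dt), self.n_windows - 1)
        if node is None:
            return dict(zip(self.node_names, self.probs[w]))
        return self.probs[w, self.node_names.index(node)]

    def final(self) -> dict[str, float]:
        return dict(zip(self.node_names, self.probs[-1]))

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (window_start, node)."""
        rows = []
        starts = self.window_starts
        for w in range(self.n_windows):
            for j, name in enumerate(self.node_names):
                rows.append((starts[w], name, self.probs[w, j]))
        return pd.DataFrame(rows, columns=["window_start", "node", "probability"])


# --------------------------------------------------------------------------
# scalar trajectory API
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """A single jump trajectory: initial state plus (time, node) flips."""

    init_state: tuple[int, ...]
    jumps: list[tuple[float, str]] = field(default_factory=list)
    t_end: float = 0.0
    node_names: list[str] = field(default_factory=list)

    def states_at(self, times: np.ndarray) -> np.ndarray:
        """Joint states at the given times (uint8, shape (len(times), n))."""
        name_idx = {n: i for i, n in enumerate(self.node_names)}
        state = np.array(self.init_state, dtype=np.uint8)
        out = np.empty((len(times), state.size), dtype=np.uint8)
        j = 0
        for k, t in enumerate(times):
            while j < len(self.jumps) and self.jumps[j][0] <= t:
                state[name_idx[self.jumps[j][1]]] ^= 1
                j += 1
            out[k] = state
        return out


def enabled_transitions(model: CompiledModel, state) -> list[tuple[str, float]]:
    """Enabled flips from a single state: list of (node, rate)."""
    if isinstance(state, dict):
        vec = np.array([state[n] for n in model.names], dtype=np.uint8)
    else:
        vec = np.asarray(state, dtype=np.uint8)
    rates = model.transition_rates(vec[None, :])[0]
    return [(model.names[i], rates[i]) for i in np.flatnonzero(rates > 0)]


def simulate_trajectory(
    model: CompiledModel,
    init_state,
    t_max: float,
    rng: np.random.Generator,
) -> Trajectory:
    """Gillespie simulation of one trajectory up to ``t_max``.

    Deterministic given ``rng``'s state; stops early at the first absorbing
    state.
    """
    if isinstance(init_state, dict):
        vec = np.array([init_state.get(n, 0) for n in model.names], dtype=np.uint8)
    else:
        vec = np.array(init_state, dtype=np.uint8)
    model.apply_clamps(vec[None, :])
    traj = Trajectory(
        init_state=tuple(int(x) for x in vec), t_end=t_max, node_names=list(model.names)
    )
    t = 0.0
    while True:
        rates = model.transition_rates(vec[None, :])[0]
        total = rates.sum()
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        r = rng.random() * total
        i = int(np.searchsorted(np.cumsum(rates), r, side="right"))
        i = min(i, model.n - 1)
        vec[i] ^= 1
        traj.jumps.append((t, model.names[i]))
    return traj


def estimate_marginals(
    trajectories: list[Trajectory],
    window_dt: float,
    weights=None,
) -> MarginalTimecourse:
    """Windowed time-averaged marginals from an explicit trajectory list.

    ``weights`` (optional) supports population reweighting; defaults to
    uniform.
    """
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    t_max = trajectories[0].t_end
    names = trajectories[0].node_names
    for tr in trajectories:
        if tr.t_end != t_max or tr.node_names != names:
            raise ValueError("trajectories must share t_max and node set")
    n_windows = int(round(t_max / window_dt))
    if abs(n_windows * window_dt - t_max) > 1e-9 * max(1.0, t_max):
        raise ValueError(f"window_dt={window_dt} does not divide t_max={t_max}")
    if weights is None:
        weights = np.full(len(trajectories), 1.0 / len(trajectories))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()

    occ = np.zeros((n_windows, len(names)))
    name_idx = {n: i for i, n in enumerate(names)}
    edges = np.arange(n_windows + 1) * window_dt
    for tr, w in zip(trajectories, weights):
        state = np.array(tr.init_state, dtype=float)
        t_prev = 0.0
        events = list(tr.jumps) + [(t_max, None)]
        for t_ev, node in events:
            t_ev = min(t_ev, t_max)
            if t_ev > t_prev:
                w0 = int(np.searchsorted(edges, t_prev, side="right")) - 1
                w1 = int(np.searchsorted(edges, t_ev, side="left")) - 1
                for wi in range(w0, w1 + 1):
                    lo = max(t_prev, edges[wi])
                    hi = min(t_ev, edges[wi + 1])
                    if hi > lo:
                        occ[wi] += w * (hi - lo) * state
            if node is not None:
                state[name_idx[node]] = 1.0 - state[name_idx[node]]
            t_prev = t_ev
    probs = occ / window_dt
    return MarginalTimecourse(
        node_names=list(names),
        window_dt=window_dt,
        probs=probs,
        n_trajectories=len(trajectories),
    )


# --------------------------------------------------------------------------
# ensemble run
# --------------------------------------------------------------------------


def window_rng(seed: int, window: int) -> np.random.Generator:
    """The stream used for reporting window ``window`` of a run."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(window)]))


def init_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _INIT_STREAM]))


def ensemble_marginals(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> MarginalTimecourse:
    """Vectorized ensemble run; windowed time-averaged marginals."""
    cfg.validate(net)
    model = CompiledModel(net, cfg.parameters)
    master = cfg.seed if seed is None else seed
    states = sample_initial_states(model, cfg.istate, cfg.n_trajectories, init_rng(master))
    weights = np.full(cfg.n_trajectories, 1.0 / cfg.n_trajectories)
    n_windows = cfg.n_windows
    probs = np.empty((n_windows, model.n))
    for w in range(n_windows):
        occ = advance_ensemble(model, states, weights, cfg.window_dt, window_rng(master, w))
        probs[w] = occ / (cfg.window_dt * weights.sum())
    return MarginalTimecourse(
        node_names=list(model.names),
        window_dt=cfg.window_dt,
        probs=probs,
        n_trajectories=cfg.n_trajectories,
    )
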