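"""Exact transient solution of the Boolean CTMC for small networks.

The joint process over ``n`` nodes is a Markov chain on ``2**n`` states
with one allowed flip per enabled node.  For small ``n`` the master
equation ``dP/dt = Q^T P`` is integrated numerically (scipy LSODA) and
windowed time-averaged marginals are obtained by quadrature over the dense
solution.  This is the reference against which the Monte-Carlo engine is
validated; it shares no code path with the Gillespie kernel beyond the
compiled rule tables.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .engine import CompiledModel
from .model import BooleanNetwork, ModelError, SimulationConfig

__all__ = [
    "generator_matrix",
    "initial_distribution",
    "marginals_at",
    "windowed_marginals",
]

_MAX_NODES = 12


def _all_states(n: int) -> np.ndarray:
    """All joint states as a (2**n, n) uint8 matrix; state s has bit i = node i."""
    s = np.arange(1 << n, dtype=np.intp)
    return ((s[:, None] >> np.arange(n)) & 1).astype(np.uint8)


def generator_matrix(model: CompiledModel) -> np.ndarray:
    """Dense CTMC generator Q (rows: from-state, columns: to-state)."""
    n = model.n
    if n > _MAX_NODES:
        raise ModelError(f"exact solver limited to {_MAX_NODES} nodes, got {n}")
    states = _all_states(n)
    rates = model.transition_rates(states)  # (2**n, n)
    S = 1 << n
    Q = np.zeros((S, S))
    src = np.arange(S, dtype=np.intp)
    for i in range(n):
        r = rates[:, i]
        dst = src ^ (1 << i)
        Q[src, dst] += r
    Q[src, src] -= Q.sum(axis=1)
    return Q


def initial_distribution(model: CompiledModel, istate: dict[str, float]) -> np.ndarray:
    """Product distribution over joint states from independent marginals."""
    n = model.n
    p = np.zeros(n)
    for name, v in istate.items():
        p[model.index[name]] = v
    for i, val in zip(model.clamp_idx, model.clamp_val):
        p[i] = float(val)
    states = _all_states(n)
    probs = np.where(states == 1, p, 1.0 - p)
    return probs.prod(axis=1)


def _solve(model: CompiledModel, p0: np.ndarray, t_max: float):
    Q = generator_matrix(model)
    QT = Q.T

    def rhs(_t, p):
        return QT @ p

    sol = solve_ivp(
        rhs, (0.0, t_max), p0, method="LSODA", rtol=1e-9, atol=1e-12, dense_output=True
    )
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    return sol


def marginals_at(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    times,
) -> np.ndarray:
    """Exact node marginals P(node active, t) at the given times.

    Returns an array of shape ``(len(times), n_nodes)`` in network node
    order.
    """
    model = CompiledModel(net, cfg.parameters)
    p0 = initial_distribution(model, cfg.istate)
    times = np.asarray(times, dtype=float)
    sol = _solve(model, p0, float(times.max()))
    states = _all_states(model.n).astype(float)
    out = np.empty((times.size, model.n))
    for k, t in enumerate(times):
        p = np.clip(sol.sol(t), 0.0, None)
        p = p / p.sum()
        out[k] = p @ states
    return out


def windowed_marginals(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    n_sub: int = 16,
) -> np.ndarray:
    """Exact time-averaged marginals per reporting window.

    Matches the estimator of :func:`boolpop.engine.ensemble_marginals`:
    the average of P(node, t) over each window of width ``cfg.window_dt``,
    computed by the trapezoid rule on ``n_sub`` subintervals.
    """
    model = CompiledModel(net, cfg.parameters)
    p0 = initial_distribution(model, cfg.istate)
    sol = _solve(model, p0, cfg.t_max)
    states = _all_states(model.n).astype(float)
    n_windows = cfg.n_windows
    out = np.empty((n_windows, model.n))
    for w in range(n_windows):
        ts = w * cfg.window_dt + np.linspace(0.0, cfg.window_dt, n_sub + 1)
        ps = np.clip(sol.sol(ts), 0.0, None)  # (S, n_sub+1)
        ps = ps / ps.sum(axis=0, keepdims=True)
        marg = ps.T @ states  # (n_sub+1, n)
        out[w] = np.trapezoid(marg, ts, axis=0) / cfg.window_dt
    return out
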