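"""Chained untreated/treated simulations and in-silico perturbation screens.

The treatment protocol: a disease trigger is applied at t=0 and the system
is simulated into its active state; at ``switch_time`` (default 300 h) the
perturbation is applied — node clamps (inhibition: fixed at 0; activation:
fixed at 1) and/or rate-parameter multipliers — and the run continues to
the evaluation time (default 600 h).  The treated arm resumes from the
untreated population state at the switch, so the two arms are identical
before it, and the per-step random streams are shared after it (common
random numbers).

Per readout the response is the percent change of activation probability,
``100 * (P_treated - P_untreated) / P_untreated``, evaluated at the end of
the run; for cell readouts the same statistic on the population size
(marginal × pop_ratio) is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BooleanNetwork, ModelError, PopulationConfig, SimulationConfig
from .population import PopulationState, PopulationTimecourse, run_population

__all__ = [
    "PerturbationSpec",
    "PerturbationResult",
    "apply_clamp",
    "response_pct",
    "chained_run",
    "screen",
    "default_readouts",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """A treatment: node clamps and/or rate-parameter multipliers.

    ``clamps`` is a tuple of (node, 0|1); ``multipliers`` a tuple of
    (parameter, factor) — e.g. a co-inhibitory scenario that increases a
    downregulation rate instead of fixing any node state.
    """

    clamps: tuple[tuple[str, int], ...] = ()
    multipliers: tuple[tuple[str, float], ...] = ()
    switch_time: float = 300.0

    def __post_init__(self):
        for node, v in self.clamps:
            if v not in (0, 1):
                raise ModelError(f"clamp value for {node!r} must be 0 or 1, got {v!r}")
        for param, f in self.multipliers:
            if not math.isfinite(f) or f < 0:
                raise ModelError(f"multiplier for ${param} must be finite and >= 0")

    @property
    def label(self) -> str:
        parts = [f"{n}={v}" for n, v in self.clamps]
        parts += [f"{p}*{f:g}" for p, f in self.multipliers]
        return "+".join(parts) if parts else "none"

    def validate(self, net: BooleanNetwork, cfg: SimulationConfig, t_max: float) -> None:
        for node, _ in self.clamps:
            if node not in net:
                raise ModelError(f"perturbation target {node!r} is not a declared node")
        for param, _ in self.multipliers:
            if param not in cfg.parameters:
                raise ModelError(f"perturbation parameter ${param} is not bound")
        if not 0.0 <= self.switch_time <= t_max:
            raise ModelError(
                f"switch_time {self.switch_time} outside the horizon [0, {t_max}]"
            )


def apply_clamp(net: BooleanNetwork, node: str, value: int) -> BooleanNetwork:
    """A mutant network with ``node`` fixed at ``value`` (no transitions)."""
    return net.clamp(node, value)


def response_pct(p_treated: float, p_wt: float) -> float:
    """Percent response: ``100 * (p_treated - p_wt) / p_wt``.

    Undefined (NaN) when the untreated probability is 0.
    """
    if p_wt == 0:
        return float("nan")
    return 100.0 * (p_treated - p_wt) / p_wt


@dataclass
class PerturbationResult:
    """Paired untreated/treated timecourses plus the response table."""

    spec: PerturbationSpec
    untreated: PopulationTimecourse
    treated: PopulationTimecourse
    responses: pd.DataFrame  # one row per readout
    readouts: list[str] = field(default_factory=list)


def default_readouts(net: BooleanNetwork) -> list[str]:
    """Clinical-proxy readouts: all cell-type and cell-state nodes."""
    return [d.name for d in net.nodes if d.node_class in ("cell", "cell_state")]


def _switch_step(switch_time: float, step_dt: float) -> int:
    k = switch_time / step_dt
    if abs(k - round(k)) > 1e-9:
        raise ModelError(
            f"switch_time {switch_time} must be a multiple of step_dt {step_dt}"
        )
    return int(round(k))


def _treated_continuation(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    popcfg: PopulationConfig,
    spec: PerturbationSpec,
    checkpoint: PopulationState,
    remaining_steps: int,
    seed: int | None,
) -> PopulationTimecourse:
    net_t = net
    for node, v in spec.clamps:
        net_t = net_t.clamp(node, v)
    params = dict(checkpoint.parameters)
    for param, f in spec.multipliers:
        params[param] = params[param] * f
    start = PopulationState(
        states=checkpoint.states.copy(),
        weights=checkpoint.weights.copy(),
        pop_ratio=checkpoint.pop_ratio,
        parameters=params,
        step_index=checkpoint.step_index,
    )
    tc, _ = run_population(
        net_t, cfg, popcfg, seed=seed, start=start, n_steps=remaining_steps
    )
    return tc


def _response_table(
    spec: PerturbationSpec,
    untreated: PopulationTimecourse,
    treated: PopulationTimecourse,
    readouts: list[str],
) -> pd.DataFrame:
    rows = []
    for node in readouts:
        p_wt = untreated.final_marginal(node)
        p_tr = treated.final_marginal(node)
        s_wt = untreated.final_size(node)
        s_tr = treated.final_size(node)
        rows.append(
            {
                "perturbation": spec.label,
                "readout": node,
                "p_untreated": p_wt,
                "p_treated": p_tr,
                "response_marginal_pct": response_pct(p_tr, p_wt),
                "size_untreated": s_wt,
                "size_treated": s_tr,
                "response_population_pct": response_pct(s_tr, s_wt),
            }
        )
    return pd.DataFrame(rows)


def chained_run(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    popcfg: PopulationConfig,
    spec: PerturbationSpec,
    readouts: list[str] | None = None,
    seed: int | None = None,
) -> PerturbationResult:
    """Untreated arm to t_max, treated arm resumed at the switch.

    Both arms are bitwise identical before ``spec.switch_time``.
    """
    t_max = popcfg.t_max
    spec.validate(net, cfg, t_max)
    switch = _switch_step(spec.switch_time, popcfg.step_dt)
    if readouts is None:
        readouts = default_readouts(net)

    untreated, checkpoint = run_population(
        net, cfg, popcfg, seed=seed, capture_step=switch
    )
    if untreated.extinct_at_step is not None and untreated.extinct_at_step < switch:
        raise PopulationExtinctBeforeSwitch(
            f"population extinct at step {untreated.extinct_at_step}, "
            f"before the switch at step {switch}"
        )
    remaining = popcfg.n_steps - switch
    if remaining == 0:
        treated = untreated
    else:
        cont = _treated_continuation(net, cfg, popcfg, spec, checkpoint, remaining, seed)
        prefix = PopulationTimecourse(
            node_names=list(untreated.node_names),
            step_dt=untreated.step_dt,
            marginals=untreated.marginals[:switch],
            end_marginals=untreated.end_marginals[:switch],
            pop_ratio=untreated.pop_ratio[: switch + 1],
            n_trajectories=untreated.n_trajectories,
        )
        treated = prefix.concat(cont) if switch > 0 else cont
    responses = _response_table(spec, untreated, treated, readouts)
    return PerturbationResult(
        spec=spec, untreated=untreated, treated=treated,
        responses=responses, readouts=list(readouts),
    )


class PopulationExtinctBeforeSwitch(RuntimeError):
    pass


def screen(
    net: BooleanNetwork,
    cfg: SimulationConfig,
    popcfg: PopulationConfig,
    candidates: list[PerturbationSpec],
    readouts: list[str] | None = None,
    seed: int | None = None,
    collapse_ligand_receptor: bool = False,
) -> pd.DataFrame:
    """Run many perturbations against one shared untreated arm.

    All candidates must share the same switch time.  With
    ``collapse_ligand_receptor`` a single-clamp candidate targeting a
    receptor is dropped when the same screen also clamps the receptor's
    ligand to the same value (inhibiting a cytokine or its receptor has
    near-identical effects, so the ligand stands for both).

    Returns one row per candidate per readout, in candidate order.
    """
    if not candidates:
        raise ModelError("empty candidate list")
    switch_times = {c.switch_time for c in candidates}
    if len(switch_times) != 1:
        raise ModelError("all candidates in a screen must share switch_time")
    if readouts is None:
        readouts = default_readouts(net)

    if collapse_ligand_receptor:
        candidates = _collapse_receptors(net, candidates)

    t_max = popcfg.t_max
    for c in candidates:
        c.validate(net, cfg, t_max)
    switch = _switch_step(candidates[0].switch_time, popcfg.step_dt)
    untreated, checkpoint = run_population(
        net, cfg, popcfg, seed=seed, capture_step=switch
    )
    remaining = popcfg.n_steps - switch
    tables = []
    for spec in candidates:
        if remaining == 0:
            treated = untreated
        else:
            cont = _treated_continuation(
                net, cfg, popcfg, spec, checkpoint, remaining, seed
            )
            prefix = PopulationTimecourse(
                node_names=list(untreated.node_names),
                step_dt=untreated.step_dt,
                marginals=untreated.marginals[:switch],
                end_marginals=untreated.end_marginals[:switch],
                pop_ratio=untreated.pop_ratio[: switch + 1],
                n_trajectories=untreated.n_trajectories,
            )
            treated = prefix.concat(cont) if switch > 0 else cont
        tables.append(_response_table(spec, untreated, treated, readouts))
    if not tables:
        return pd.DataFrame(
            columns=[
                "perturbation", "readout", "p_untreated", "p_treated",
                "response_marginal_pct", "size_untreated", "size_treated",
                "response_population_pct",
            ]
        )
    return pd.concat(tables, ignore_index=True)


def _collapse_receptors(
    net: BooleanNetwork, candidates: list[PerturbationSpec]
) -> list[PerturbationSpec]:
    """Drop single-clamp receptor candidates shadowed by their ligand."""
    from . import expr as _expr

    ligand_of: dict[str, str] = {}
    for decl in net.nodes:
        if decl.node_class != "receptor":
            continue
        regs = [r for r in _expr.bool_regulators(decl.logic)
                if net.node(r).node_class == "ligand"]
        if len(regs) == 1:
            ligand_of[decl.name] = regs[0]

    present = {
        (c.clamps[0][0], c.clamps[0][1])
        for c in candidates
        if len(c.clamps) == 1 and not c.multipliers
    }
    out = []
    for c in candidates:
        if len(c.clamps) == 1 and not c.multipliers:
            node, v = c.clamps[0]
            lig = ligand_of.get(node)
            if lig is not None and (lig, v) in present:
                continue
        out.append(c)
    return out
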