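"""Domain types: Boolean networks, rate configurations, population settings.

A :class:`BooleanNetwork` is a list of :class:`NodeDecl` plus optional
designated utility nodes (Division, Death, Trigger) and a clamp map.  Each
node carries a Boolean update rule, symbolic activation/inactivation rate
expressions, and a node-class annotation from the multiscale vocabulary
(cell types, cell states, ligands, receptors, transcription factors,
intermediate signaling entities, and utility nodes).  A node is considered
druggable exactly when it is a ligand, a receptor, or a transcription
factor — cell-type and cell-state nodes are not directly targetable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

from . import expr

__all__ = [
    "NODE_CLASSES",
    "DRUGGABLE_CLASSES",
    "ModelError",
    "NodeDecl",
    "BooleanNetwork",
    "SimulationConfig",
    "PopulationConfig",
]

NODE_CLASSES = (
    "cell",
    "cell_state",
    "ligand",
    "receptor",
    "transcription_factor",
    "signaling",
    "utility",
)

DRUGGABLE_CLASSES = frozenset({"ligand", "receptor", "transcription_factor"})


class ModelError(ValueError):
    """A structural problem with a network, config or population setup."""


@dataclass(frozen=True)
class NodeDecl:
    """One node: name, Boolean rule, rate expressions, class annotation."""

    name: str
    logic: tuple
    rate_up: tuple
    rate_down: tuple
    node_class: str = "signaling"

    def __post_init__(self):
        if self.node_class not in NODE_CLASSES:
            raise ModelError(
                f"node {self.name!r}: unknown node_class {self.node_class!r} "
                f"(expected one of {', '.join(NODE_CLASSES)})"
            )

    @property
    def druggable(self) -> bool:
        """True iff the node is a ligand, receptor or transcription factor."""
        return self.node_class in DRUGGABLE_CLASSES

    @property
    def inputs(self) -> tuple[str, ...]:
        """Regulators referenced by the rule, in sorted order."""
        return tuple(sorted(expr.bool_regulators(self.logic)))


@dataclass
class BooleanNetwork:
    """An ordered collection of node declarations with utility designations.

    ``clamps`` maps node name -> forced state (0 or 1); clamped nodes never
    transition and are reported at their clamped value from t=0 of any run
    using this network object.
    """

    nodes: list[NodeDecl]
    division_node: str | None = None
    death_node: str | None = None
    trigger_node: str | None = None
    clamps: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- lookups ----------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ModelError(f"unknown node {name!r}") from None

    def node(self, name: str) -> NodeDecl:
        return self.nodes[self.index(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.nodes)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        names = self.names
        seen = set()
        for n in names:
            if n in seen:
                raise ModelError(f"duplicate node {n!r}")
            seen.add(n)
        for decl in self.nodes:
            for ref in expr.bool_regulators(decl.logic):
                if ref not in seen:
                    raise ModelError(
                        f"rule of {decl.name!r} references undeclared node {ref!r}"
                    )
        for label, value in (
            ("division_node", self.division_node),
            ("death_node", self.death_node),
            ("trigger_node", self.trigger_node),
        ):
            if value is not None and value not in seen:
                raise ModelError(f"{label} {value!r} is not a declared node")
        for name, v in self.clamps.items():
            if name not in seen:
                raise ModelError(f"clamped node {name!r} is not declared")
            if v not in (0, 1):
                raise ModelError(f"clamp value for {name!r} must be 0 or 1, got {v!r}")

    # -- derived ----------------------------------------------------------

    def rate_symbols(self) -> set[str]:
        """All $parameter symbols referenced by any rate expression."""
        out: set[str] = set()
        for decl in self.nodes:
            out |= expr.arith_params(decl.rate_up)
            out |= expr.arith_params(decl.rate_down)
        return out

    def clamp(self, node: str, value: int) -> "BooleanNetwork":
        """Return a copy of the network with ``node`` clamped to ``value``."""
        if node not in self:
            raise ModelError(f"cannot clamp unknown node {node!r}")
        clamps = dict(self.clamps)
        clamps[node] = int(value)
        return dataclasses.replace(self, clamps=clamps)


@dataclass
class SimulationConfig:
    """Monte-Carlo settings and rate-parameter values.

    ``istate`` maps node -> probability of being active at t=0 (independent
    marginals; unlisted nodes start inactive).  Time is in hours and rates
    are per hour.
    """

    parameters: dict[str, float] = field(default_factory=dict)
    istate: dict[str, float] = field(default_factory=dict)
    n_trajectories: int = 50_000
    t_max: float = 200.0
    window_dt: float = 1.0
    seed: int = 0
    defaults_applied: list[str] = field(default_factory=list, repr=False, compare=False)

    def validate(self, net: BooleanNetwork | None = None) -> None:
        if self.n_trajectories < 1:
            raise ModelError(f"n_trajectories must be >= 1, got {self.n_trajectories}")
        if self.window_dt <= 0 or self.t_max <= 0:
            raise ModelError("t_max and window_dt must be positive")
        ratio = self.t_max / self.window_dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ModelError(
                f"window_dt={self.window_dt} does not divide t_max={self.t_max}"
            )
        for node, p in self.istate.items():
            if not 0.0 <= p <= 1.0:
                raise ModelError(f"initial probability of {node!r} is {p}, not in [0,1]")
            if net is not None and node not in net:
                raise ModelError(f"istate references undeclared node {node!r}")
        for name, v in self.parameters.items():
            if not math.isfinite(v):
                raise ModelError(f"parameter ${name} is not finite: {v}")
        if net is not None:
            unbound = net.rate_symbols() - set(self.parameters)
            if unbound:
                raise ModelError(
                    "unbound rate parameters: " + ", ".join(sorted("$" + s for s in unbound))
                )
            # every rate must evaluate to a nonnegative finite number
            for decl in net.nodes:
                for which, ast in (("rate_up", decl.rate_up), ("rate_down", decl.rate_down)):
                    v = expr.arith_eval(ast, self.parameters)
                    if not math.isfinite(v) or v < 0:
                        raise ModelError(
                            f"{which} of {decl.name!r} evaluates to {v}; rates must be "
                            "finite and nonnegative"
                        )

    @property
    def n_windows(self) -> int:
        return int(round(self.t_max / self.window_dt))

    def with_parameter(self, name: str, value: float) -> "SimulationConfig":
        params = dict(self.parameters)
        params[name] = value
        return dataclasses.replace(self, parameters=params)


@dataclass
class PopulationConfig:
    """Settings for the synchronous population layer.

    ``update_rules`` is a list of ``(parameter, formula AST)`` pairs; after
    every population step each listed parameter is recomputed from the
    end-of-step node marginals (``p[Node]``) and the current ``pop_ratio``.
    ``death_precedence`` resolves states carrying both Division=1 and
    Death=1: when True (default) such a state dies; when False it divides
    and survives.
    """

    n_steps: int = 200
    step_dt: float = 1.0
    division_node: str | None = None
    death_node: str | None = None
    update_rules: list[tuple[str, tuple]] = field(default_factory=list)
    death_precedence: bool = True
    resample_ess: float = 0.5

    def validate(self, net: BooleanNetwork | None = None,
                 cfg: SimulationConfig | None = None) -> None:
        if self.step_dt <= 0:
            raise ModelError(f"step_dt must be positive, got {self.step_dt}")
        if self.n_steps < 1:
            raise ModelError(f"n_steps must be >= 1, got {self.n_steps}")
        if net is not None:
            for label, v in (("division", self.division_node), ("death", self.death_node)):
                if v is not None and v not in net:
                    raise ModelError(f"{label} node {v!r} is not declared in the network")
            for param, ast in self.update_rules:
                for ref in expr.arith_probs(ast):
                    if ref not in net:
                        raise ModelError(
                            f"update rule for ${param} references unknown node {ref!r}"
                        )
        if cfg is not None:
            for param, ast in self.update_rules:
                missing = expr.arith_params(ast) - set(cfg.parameters)
                if missing:
                    raise ModelError(
                        f"update rule for ${param} references unbound "
                        + ", ".join(sorted("$" + m for m in missing))
                    )

    @property
    def t_max(self) -> float:
        return self.n_steps * self.step_dt
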