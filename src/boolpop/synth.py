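"""Synthetic models: analytic CTMC cases, toy multiscale disease models,
and random signed digraphs.

Three families of test surfaces:

* Analytic cases whose exact behavior has a closed form (exponential
  activation, pure birth/death population laws) or is computable by the
  small-state master equation — used to validate the Monte-Carlo engine
  and the population layer against independent mathematics.
* Toy multiscale models emulating the architecture of the psoriasis-style
  disease model: a persistent trigger, an activated-cell layer, ligand ->
  receptor -> transcription-factor chains, a proliferating cell state
  wired to Division/Death, optional cross-layer feedback loops, and
  receptor activation rates recomputed each population step from ligand
  probabilities.
* Erdős–Rényi signed digraphs for exhaustive FVS oracle testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from . import expr
from .model import BooleanNetwork, NodeDecl, PopulationConfig, SimulationConfig

__all__ = [
    "AnalyticCase",
    "ANALYTIC_CASES",
    "make_analytic_case",
    "make_toy_multiscale",
    "make_random_digraph",
    "network_from_rules",
]


def network_from_rules(
    rules: dict[str, tuple],
    classes: dict[str, str] | None = None,
    division_node: str | None = None,
    death_node: str | None = None,
    trigger_node: str | None = None,
) -> tuple[BooleanNetwork, dict[str, float]]:
    """Build a network from ``{name: (logic_text, k_up, k_down)}``.

    Rates become symbolic parameters ``$k_<name>_up`` / ``$k_<name>_down``;
    the returned parameter dict binds them.  Convenience constructor used
    by the generators and throughout the test-suite.
    """
    classes = classes or {}
    nodes = []
    params: dict[str, float] = {}
    for name, (logic_text, k_up, k_down) in rules.items():
        up_sym, down_sym = f"k_{name}_up", f"k_{name}_down"
        params[up_sym] = float(k_up)
        params[down_sym] = float(k_down)
        nodes.append(
            NodeDecl(
                name=name,
                logic=expr.parse_bool(logic_text),
                rate_up=("param", up_sym),
                rate_down=("param", down_sym),
                node_class=classes.get(name, "signaling"),
            )
        )
    net = BooleanNetwork(
        nodes=nodes,
        division_node=division_node,
        death_node=death_node,
        trigger_node=trigger_node,
    )
    return net, params


@dataclass
class AnalyticCase:
    """A model whose exact behavior is known independently of the engine."""

    name: str
    net: BooleanNetwork
    cfg: SimulationConfig
    popcfg: PopulationConfig | None
    readout: str  # "marginal:<node>" or "pop_ratio"
    expected: Callable[[float], float]  # exact value at time t
    description: str


ANALYTIC_CASES = (
    "exponential_activation",
    "birth_growth",
    "death_decay",
    "two_node_master_equation",
)


def make_analytic_case(
    name: str,
    n_trajectories: int = 50_000,
    seed: int = 0,
) -> AnalyticCase:
    """Build one of the named closed-form validation cases."""
    if name == "exponential_activation":
        # single node with a constant-true rule: P_on(t) = 1 - exp(-k t)
        k = 1.0
        net, params = network_from_rules({"A": ("TRUE", k, 1.0)})
        cfg = SimulationConfig(
            parameters=params, istate={}, n_trajectories=n_trajectories,
            t_max=10.0, window_dt=1.0, seed=seed,
        )
        return AnalyticCase(
            name=name, net=net, cfg=cfg, popcfg=None, readout="marginal:A",
            expected=lambda t, k=k: 1.0 - math.exp(-k * t),
            description=f"constant-true node, k_up={k}: P(t) = 1 - exp(-{k} t)",
        )
    if name == "birth_growth":
        # cell always alive; Division fires at rate d; no death:
        # pop_ratio(T) -> exp(d T) as step_dt -> 0
        d = 0.05
        net, params = network_from_rules(
            {"Cell": ("TRUE", 1.0, 0.0), "Division": ("Cell", d, 0.0)},
            classes={"Cell": "cell", "Division": "utility"},
            division_node="Division",
        )
        cfg = SimulationConfig(
            parameters=params, istate={"Cell": 1.0}, n_trajectories=n_trajectories,
            t_max=100.0, window_dt=0.1, seed=seed,
        )
        popcfg = PopulationConfig(
            n_steps=1000, step_dt=0.1, division_node="Division", death_node=None,
        )
        return AnalyticCase(
            name=name, net=net, cfg=cfg, popcfg=popcfg, readout="pop_ratio",
            expected=lambda t, d=d: math.exp(d * t),
            description=f"pure birth process, d={d}: pop_ratio(T) ~ exp({d} T)",
        )
    if name == "death_decay":
        m = 0.05
        net, params = network_from_rules(
            {"Cell": ("TRUE", 1.0, 0.0), "Death": ("Cell", m, 0.0)},
            classes={"Cell": "cell", "Death": "utility"},
            death_node="Death",
        )
        cfg = SimulationConfig(
            parameters=params, istate={"Cell": 1.0}, n_trajectories=n_trajectories,
            t_max=100.0, window_dt=0.1, seed=seed,
        )
        popcfg = PopulationConfig(
            n_steps=1000, step_dt=0.1, division_node=None, death_node="Death",
        )
        return AnalyticCase(
            name=name, net=net, cfg=cfg, popcfg=popcfg, readout="pop_ratio",
            expected=lambda t, m=m: math.exp(-m * t),
            description=f"pure death process, m={m}: pop_ratio(T) ~ exp(-{m} T)",
        )
    if name == "two_node_master_equation":
        # A switches on at rate 0.9; B follows A with asymmetric rates and
        # keeps toggling — the 4-state master equation is the reference.
        net, params = network_from_rules(
            {"A": ("TRUE", 0.9, 1.0), "B": ("A", 1.3, 0.4)}
        )
        cfg = SimulationConfig(
            parameters=params, istate={}, n_trajectories=n_trajectories,
            t_max=10.0, window_dt=1.0, seed=seed,
        )
        from . import exact

        def expected(t: float) -> float:
            return float(exact.marginals_at(net, cfg, [t])[0, net.index("B")])

        return AnalyticCase(
            name=name, net=net, cfg=cfg, popcfg=None, readout="marginal:B",
            expected=expected,
            description="two-node relay A -> B, reference = 4-state master equation",
        )
    raise ValueError(f"unknown analytic case {name!r} (choose from {ANALYTIC_CASES})")


def make_toy_multiscale(
    n_cells: int = 1,
    n_ligand_chains: int = 1,
    feedback: bool = True,
    seed: int = 0,
) -> tuple[BooleanNetwork, SimulationConfig, PopulationConfig]:
    """A small disease-architecture model for end-to-end tests.

    Wiring: a persistent Trigger activates an activated-cell node (aKC
    analog); each ligand chain runs ligand -> receptor -> transcription
    factor; the proliferating cell state requires every chain's
    transcription factor; Division is driven by the proliferating state
    and Death by its absence.  With ``feedback`` the proliferating state
    feeds back onto every ligand, closing cell/signaling loops
    (self-sustained disease state).  Receptor activation rates are
    declared as population-step update rules on their ligand's
    probability.  Extra ``n_cells - 1`` immune-cell analogs listen to the
    first ligand.

    Rates are log-uniform in class-typical ranges, reproducible under
    ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_ligand_chains < 1:
        raise ValueError("n_ligand_chains must be >= 1")
    rng = np.random.default_rng(seed)

    def rate(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    rules: dict[str, tuple] = {}
    classes: dict[str, str] = {}

    rules["Trigger"] = ("Trigger", 0.0, 0.0)  # frozen at its initial value
    classes["Trigger"] = "utility"
    rules["ACell"] = ("Trigger", rate(0.5, 2.0), rate(0.05, 0.2))
    classes["ACell"] = "cell"

    tf_names = []
    for i in range(n_ligand_chains):
        lig, rec, tf = f"Lig{i}", f"Rec{i}", f"TF{i}"
        src = f"ACell OR Prol" if feedback else "ACell"
        rules[lig] = (src, rate(1.0, 3.0), rate(3.0, 8.0))  # fast ligand decay
        classes[lig] = "ligand"
        # receptor k_up is a placeholder; the update rule recomputes it
        rules[rec] = (lig, 1.0, rate(0.5, 1.5))
        classes[rec] = "receptor"
        rules[tf] = (rec, rate(0.5, 2.0), rate(0.2, 0.8))
        classes[tf] = "transcription_factor"
        tf_names.append(tf)

    rules["Prol"] = (" AND ".join(tf_names), rate(0.5, 1.5), rate(0.1, 0.4))
    classes["Prol"] = "cell_state"
    rules["Division"] = ("Prol", 0.05, 0.0)
    classes["Division"] = "utility"
    rules["Death"] = ("NOT Prol", 0.02, 0.0)
    classes["Death"] = "utility"

    for j in range(1, n_cells):
        name = f"Imm{j}"
        rules[name] = ("Lig0", rate(0.3, 1.0), rate(0.1, 0.5))
        classes[name] = "cell"

    net, params = network_from_rules(
        rules,
        classes=classes,
        division_node="Division",
        death_node="Death",
        trigger_node="Trigger",
    )
    update_rules = []
    for i in range(n_ligand_chains):
        c_sym = f"c_Rec{i}"
        params[c_sym] = rate(1.0, 3.0)
        params[f"k_Rec{i}_up"] = params[c_sym]  # consistent starting value
        update_rules.append(
            (f"k_Rec{i}_up", ("mul", ("param", c_sym), ("prob", f"Lig{i}")))
        )
    cfg = SimulationConfig(
        parameters=params,
        istate={"Trigger": 1.0},
        n_trajectories=5_000,
        t_max=60.0,
        window_dt=1.0,
        seed=seed,
    )
    popcfg = PopulationConfig(
        n_steps=60,
        step_dt=1.0,
        division_node="Division",
        death_node="Death",
        update_rules=update_rules,
    )
    cfg.validate(net)
    popcfg.validate(net, cfg)
    return net, cfg, popcfg


def make_random_digraph(n: int, edge_prob: float, seed: int = 0) -> nx.MultiDiGraph:
    """Erdős–Rényi directed graph with random edge signs, reproducible.

    Node names are ``n0 .. n<n-1>``; all nodes are annotated druggable
    ligands by default so the graph is directly usable in ranking tests.
    """
    rng = np.random.default_rng(seed)
    g = nx.MultiDiGraph()
    names = [f"n{i}" for i in range(n)]
    for name in names:
        g.add_node(name, node_class="ligand", druggable=True)
    for u in names:
        for v in names:
            if u != v and rng.random() < edge_prob:
                g.add_edge(u, v, sign=1 if rng.random() < 0.7 else -1)
    return g
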