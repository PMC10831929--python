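"""Reading and writing the textual model dialect and influence graphs.

Three file kinds make up a model:

``.bnd`` — node declarations::

    // comment
    trigger = Trigger;
    node AMP {
      logic = Prol_KC AND STAT3;
      rate_up = $k_AMP_up;
      rate_down = $k_AMP_down;
      class = signaling;        // optional, defaults to "signaling"
    }

``.cfg`` — parameter values, initial state and Monte-Carlo settings::

    $k_AMP_up = 0.1;
    Trigger.istate = 1;
    n_trajectories = 50000;
    t_max = 200;  window_dt = 1;  seed = 42;

``.upp`` — population layer: Division/Death designation, step count, and
per-step rate-update formulas::

    division = Division;
    death = Death;
    steps = 200;  step_dt = 1;
    $k_IL10R_up u= $c_IL10R * p[IL10];

The influence graph derived from the rules is a signed directed multigraph
(one edge per regulator/target/sign triple; a regulator appearing under
both polarities yields two opposite-signed edges).  It can be exported as
SIF (``source <tab> +/- <tab> target``) or GraphML, with a TSV side-file
for node-class/druggability annotations.
"""

from __future__ import annotations

import io
import re

import networkx as nx

from . import expr
from .expr import ParseError
from .model import (
    DRUGGABLE_CLASSES,
    NODE_CLASSES,
    BooleanNetwork,
    ModelError,
    NodeDecl,
    PopulationConfig,
    SimulationConfig,
)

__all__ = [
    "parse_logic_file",
    "parse_config",
    "parse_population_file",
    "write_logic_file",
    "write_config",
    "write_population_file",
    "write_model",
    "read_model",
    "influence_graph",
    "write_sif",
    "read_sif",
    "write_graphml",
    "write_annotations",
    "read_annotations",
    "apply_annotations",
]

_COMMENT_RE = re.compile(r"//.*|#.*")


def _lines(text: str):
    """Yield (lineno, stripped content) with comments removed."""
    for i, raw in enumerate(text.splitlines(), start=1):
        line = _COMMENT_RE.sub("", raw).strip()
        if line:
            yield i, line


def _statements(text: str):
    """Split on ';', tracking the line each statement starts on."""
    for lineno, line in _lines(text):
        for stmt in line.split(";"):
            stmt = stmt.strip()
            if stmt:
                yield lineno, stmt


# --------------------------------------------------------------------------
# .bnd
# --------------------------------------------------------------------------

_NODE_HEAD_RE = re.compile(r"^node\s+([A-Za-z_]\w*)\s*(\{)?\s*(.*)$")
_TOP_RE = re.compile(r"^(trigger|division|death)\s*=\s*([A-Za-z_]\w*)\s*;?\s*$")
_FIELD_RE = re.compile(r"^(logic|rate_up|rate_down|class)\s*=\s*(.+?)\s*;?\s*$")


def parse_logic_file(text: str) -> BooleanNetwork:
    """Parse a ``.bnd`` node-declaration file into a validated network."""
    nodes: list[NodeDecl] = []
    tops: dict[str, str] = {}
    it = iter(_lines(text))
    while True:
        try:
            lineno, line = next(it)
        except StopIteration:
            break
        m = _TOP_RE.match(line)
        if m:
            tops[m.group(1)] = m.group(2)
            continue
        m = _NODE_HEAD_RE.match(line)
        if not m:
            raise ParseError(
                f"expected 'node NAME {{' or a top-level declaration, got {line!r}",
                lineno,
            )
        name, brace, rest = m.group(1), m.group(2), m.group(3).strip()
        if brace is None:
            if rest:
                raise ParseError(f"expected '{{' after 'node {name}', got {rest!r}", lineno)
            try:
                lineno2, line2 = next(it)
            except StopIteration:
                raise ParseError(f"unterminated declaration of node {name!r}", lineno)
            if not line2.startswith("{"):
                raise ParseError(f"expected '{{' after 'node {name}', got {line2!r}", lineno2)
            rest = line2[1:].strip()
        # body pieces: the remainder of the header line, then following lines
        fields: dict[str, tuple[int, str]] = {}
        closed = False
        body_iter: list[tuple[int, str]] = [(lineno, rest)]
        body_lineno = lineno
        while not closed:
            if body_iter:
                body_lineno, body = body_iter.pop(0)
            else:
                try:
                    body_lineno, body = next(it)
                except StopIteration:
                    raise ParseError(f"missing '}}' for node {name!r}", lineno)
            body = body.strip()
            if body.endswith("}"):
                body, closed = body[:-1].strip(), True
            for stmt in body.split(";"):
                stmt = stmt.strip()
                if not stmt:
                    continue
                fm = _FIELD_RE.match(stmt)
                if not fm:
                    raise ParseError(f"bad field {stmt!r} in node {name!r}", body_lineno)
                key = fm.group(1)
                if key in fields:
                    raise ParseError(f"duplicate field {key!r} in node {name!r}", body_lineno)
                fields[key] = (body_lineno, fm.group(2))
        if "logic" not in fields:
            raise ParseError(f"node {name!r} has no logic rule", lineno)
        lln, ltext = fields["logic"]
        logic = expr.parse_bool(ltext, lln)
        uln, utext = fields.get("rate_up", (lineno, "1"))
        dln, dtext = fields.get("rate_down", (lineno, "1"))
        node_class = fields.get("class", (lineno, "signaling"))[1].strip()
        try:
            decl = NodeDecl(
                name=name,
                logic=logic,
                rate_up=expr.parse_arith(utext, uln),
                rate_down=expr.parse_arith(dtext, dln),
                node_class=node_class,
            )
        except ModelError as e:
            raise ParseError(str(e), lineno) from None
        if any(n.name == name for n in nodes):
            raise ParseError(f"duplicate node {name!r}", lineno)
        nodes.append(decl)
    if not nodes:
        raise ParseError("no node declarations found")
    try:
        return BooleanNetwork(
            nodes=nodes,
            division_node=tops.get("division"),
            death_node=tops.get("death"),
            trigger_node=tops.get("trigger"),
        )
    except ModelError as e:
        raise ParseError(str(e)) from None


def write_logic_file(net: BooleanNetwork) -> str:
    buf = io.StringIO()
    for label, v in (
        ("trigger", net.trigger_node),
        ("division", net.division_node),
        ("death", net.death_node),
    ):
        if v is not None:
            buf.write(f"{label} = {v};\n")
    for decl in net.nodes:
        buf.write(f"node {decl.name} {{\n")
        buf.write(f"  logic = {expr.bool_to_str(decl.logic)};\n")
        buf.write(f"  rate_up = {expr.arith_to_str(decl.rate_up)};\n")
        buf.write(f"  rate_down = {expr.arith_to_str(decl.rate_down)};\n")
        buf.write(f"  class = {decl.node_class};\n")
        buf.write("}\n")
    return buf.getvalue()


# --------------------------------------------------------------------------
# .cfg
# --------------------------------------------------------------------------

_PARAM_RE = re.compile(r"^\$([A-Za-z_]\w*)\s*=\s*(.+)$")
_ISTATE_RE = re.compile(r"^([A-Za-z_]\w*)\.istate\s*=\s*(.+)$")
_SETTING_RE = re.compile(r"^(n_trajectories|t_max|window_dt|seed)\s*=\s*(.+)$")

_CFG_DEFAULTS = {"n_trajectories": 50_000, "t_max": 200.0, "window_dt": 1.0, "seed": 0}


def parse_config(text: str, net: BooleanNetwork) -> SimulationConfig:
    """Parse a ``.cfg`` file and validate it against ``net``.

    Unset Monte-Carlo settings receive documented defaults which are
    recorded in ``config.defaults_applied``.
    """
    parameters: dict[str, float] = {}
    istate: dict[str, float] = {}
    settings: dict[str, float] = {}
    for lineno, stmt in _statements(text):
        m = _PARAM_RE.match(stmt)
        if m:
            try:
                parameters[m.group(1)] = float(m.group(2))
            except ValueError:
                raise ParseError(f"bad numeric value for ${m.group(1)}: {m.group(2)!r}", lineno)
            continue
        m = _ISTATE_RE.match(stmt)
        if m:
            try:
                istate[m.group(1)] = float(m.group(2))
            except ValueError:
                raise ParseError(f"bad istate value for {m.group(1)}: {m.group(2)!r}", lineno)
            continue
        m = _SETTING_RE.match(stmt)
        if m:
            try:
                settings[m.group(1)] = float(m.group(2))
            except ValueError:
                raise ParseError(f"bad value for {m.group(1)}: {m.group(2)!r}", lineno)
            continue
        raise ParseError(f"unrecognized config statement {stmt!r}", lineno)
    defaults_applied = [k for k in _CFG_DEFAULTS if k not in settings]
    merged = {**_CFG_DEFAULTS, **settings}
    cfg = SimulationConfig(
        parameters=parameters,
        istate=istate,
        n_trajectories=int(merged["n_trajectories"]),
        t_max=float(merged["t_max"]),
        window_dt=float(merged["window_dt"]),
        seed=int(merged["seed"]),
        defaults_applied=defaults_applied,
    )
    cfg.validate(net)
    return cfg


def write_config(cfg: SimulationConfig) -> str:
    buf = io.StringIO()
    for name in sorted(cfg.parameters):
        buf.write(f"${name} = {cfg.parameters[name]!r};\n")
    for node in sorted(cfg.istate):
        buf.write(f"{node}.istate = {cfg.istate[node]!r};\n")
    buf.write(f"n_trajectories = {cfg.n_trajectories};\n")
    buf.write(f"t_max = {cfg.t_max!r};\n")
    buf.write(f"window_dt = {cfg.window_dt!r};\n")
    buf.write(f"seed = {cfg.seed};\n")
    return buf.getvalue()


# --------------------------------------------------------------------------
# .upp
# --------------------------------------------------------------------------

_UPP_SETTING_RE = re.compile(r"^(division|death)\s*=\s*([A-Za-z_]\w*)$")
_UPP_NUM_RE = re.compile(r"^(steps|step_dt|resample_ess)\s*=\s*(.+)$")
_UPP_BOOL_RE = re.compile(r"^death_precedence\s*=\s*(true|false)$", re.IGNORECASE)
_UPP_UPDATE_RE = re.compile(r"^\$([A-Za-z_]\w*)\s*u=\s*(.+)$")


def parse_population_file(text: str, net: BooleanNetwork) -> PopulationConfig:
    """Parse a ``.upp`` population-layer file and validate it against ``net``."""
    kw: dict[str, object] = {}
    update_rules: list[tuple[str, tuple]] = []
    for lineno, stmt in _statements(text):
        m = _UPP_UPDATE_RE.match(stmt)
        if m:
            update_rules.append((m.group(1), expr.parse_arith(m.group(2), lineno)))
            continue
        m = _UPP_SETTING_RE.match(stmt)
        if m:
            kw[f"{m.group(1)}_node"] = m.group(2)
            continue
        m = _UPP_NUM_RE.match(stmt)
        if m:
            key = {"steps": "n_steps"}.get(m.group(1), m.group(1))
            try:
                v = float(m.group(2))
            except ValueError:
                raise ParseError(f"bad value for {m.group(1)}: {m.group(2)!r}", lineno)
            kw[key] = int(v) if key == "n_steps" else v
            continue
        m = _UPP_BOOL_RE.match(stmt)
        if m:
            kw["death_precedence"] = m.group(1).lower() == "true"
            continue
        raise ParseError(f"unrecognized population statement {stmt!r}", lineno)
    popcfg = PopulationConfig(update_rules=update_rules, **kw)
    popcfg.validate(net)
    return popcfg


def write_population_file(popcfg: PopulationConfig) -> str:
    buf = io.StringIO()
    if popcfg.division_node:
        buf.write(f"division = {popcfg.division_node};\n")
    if popcfg.death_node:
        buf.write(f"death = {popcfg.death_node};\n")
    buf.write(f"steps = {popcfg.n_steps};\n")
    buf.write(f"step_dt = {popcfg.step_dt!r};\n")
    buf.write(f"death_precedence = {'true' if popcfg.death_precedence else 'false'};\n")
    for param, ast in popcfg.update_rules:
        buf.write(f"${param} u= {expr.arith_to_str(ast)};\n")
    return buf.getvalue()


# --------------------------------------------------------------------------
# bundles
# --------------------------------------------------------------------------


def write_model(net, cfg=None, popcfg=None, prefix=None):
    """Write a model bundle to ``<prefix>.bnd/.cfg/.upp``; return the paths."""
    if prefix is None:
        raise ValueError("prefix is required")
    prefix = str(prefix)
    paths = {}
    with open(prefix + ".bnd", "w") as fh:
        fh.write(write_logic_file(net))
    paths["bnd"] = prefix + ".bnd"
    if cfg is not None:
        with open(prefix + ".cfg", "w") as fh:
            fh.write(write_config(cfg))
        paths["cfg"] = prefix + ".cfg"
    if popcfg is not None:
        with open(prefix + ".upp", "w") as fh:
            fh.write(write_population_file(popcfg))
        paths["upp"] = prefix + ".upp"
    return paths


def read_model(bnd_path, cfg_path=None, upp_path=None):
    """Read a model bundle; returns (net, cfg or None, popcfg or None)."""
    with open(bnd_path) as fh:
        net = parse_logic_file(fh.read())
    cfg = popcfg = None
    if cfg_path is not None:
        with open(cfg_path) as fh:
            cfg = parse_config(fh.read(), net)
    if upp_path is not None:
        with open(upp_path) as fh:
            popcfg = parse_population_file(fh.read(), net)
        if popcfg.division_node and net.division_node is None:
            net.division_node = popcfg.division_node
        if popcfg.death_node and net.death_node is None:
            net.death_node = popcfg.death_node
    return net, cfg, popcfg


# --------------------------------------------------------------------------
# influence graph
# --------------------------------------------------------------------------


def influence_graph(net: BooleanNetwork, include_utility: bool = True) -> nx.MultiDiGraph:
    """Signed influence graph: edge u->v with sign s iff u appears in v's
    rule with syntactic polarity s (sign -1 under an odd number of NOTs).

    With ``include_utility=False`` the designated Division/Death/Trigger
    nodes are dropped — they are population-layer plumbing, not disease
    circuitry.
    """
    g = nx.MultiDiGraph()
    skip = set()
    if not include_utility:
        skip = {net.division_node, net.death_node, net.trigger_node} - {None}
    for decl in net.nodes:
        if decl.name in skip:
            continue
        g.add_node(decl.name, node_class=decl.node_class, druggable=decl.druggable)
    for decl in net.nodes:
        if decl.name in skip:
            continue
        for reg, signs in expr.bool_regulators(decl.logic).items():
            if reg in skip:
                continue
            for sign in sorted(signs, reverse=True):
                g.add_edge(reg, decl.name, sign=sign)
    return g


_SIF_SIGN = {1: "+", -1: "-"}
_SIF_SIGN_INV = {"+": 1, "-": -1, "activates": 1, "inhibits": -1, "1": 1, "-1": -1}


def write_sif(g: nx.MultiDiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{_SIF_SIGN[data.get('sign', 1)]}\t{v}\n")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")


def read_sif(path) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 1:
                g.add_node(parts[0])
            elif len(parts) == 3:
                src, rel, dst = parts
                if rel not in _SIF_SIGN_INV:
                    raise ParseError(f"unknown SIF relation {rel!r}", lineno)
                g.add_edge(src, dst, sign=_SIF_SIGN_INV[rel])
            else:
                raise ParseError(f"malformed SIF line {line!r}", lineno)
    return g


def write_graphml(g: nx.MultiDiGraph, path) -> None:
    h = nx.MultiDiGraph()
    for n, data in g.nodes(data=True):
        h.add_node(n, **{k: str(v) for k, v in data.items()})
    for u, v, data in g.edges(data=True):
        h.add_edge(u, v, sign=str(data.get("sign", 1)))
    nx.write_graphml(h, path)


# --------------------------------------------------------------------------
# node-class annotations (TSV side-file)
# --------------------------------------------------------------------------


def write_annotations(net: BooleanNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tnode_class\tdruggable\n")
        for decl in net.nodes:
            fh.write(f"{decl.name}\t{decl.node_class}\t{str(decl.druggable).lower()}\n")


def read_annotations(path) -> dict[str, str]:
    """Read a node/class TSV; returns ``{node: node_class}``.

    A ``druggable`` column, if present, is checked for consistency with the
    class (druggability is a pure function of node_class).
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        try:
            i_node, i_class = header.index("node"), header.index("node_class")
        except ValueError:
            raise ParseError(f"annotation header must contain 'node' and 'node_class', got {header}")
        i_drug = header.index("druggable") if "druggable" in header else None
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            node, node_class = parts[i_node], parts[i_class]
            if node_class not in NODE_CLASSES:
                raise ParseError(f"unknown node_class {node_class!r} for {node!r}", lineno)
            if i_drug is not None:
                claimed = parts[i_drug].strip().lower() in ("true", "1", "yes")
                actual = node_class in DRUGGABLE_CLASSES
                if claimed != actual:
                    raise ParseError(
                        f"druggable={parts[i_drug]!r} inconsistent with class "
                        f"{node_class!r} for node {node!r}",
                        lineno,
                    )
            out[node] = node_class
    return out


def apply_annotations(net: BooleanNetwork, classes: dict[str, str]) -> BooleanNetwork:
    """Return a copy of ``net`` with node classes replaced from a mapping."""
    import dataclasses as _dc

    nodes = []
    for decl in net.nodes:
        if decl.name in classes:
            decl = _dc.replace(decl, node_class=classes[decl.name])
        nodes.append(decl)
    return _dc.replace(net, nodes=nodes)
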