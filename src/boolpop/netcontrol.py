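"""Feedback-vertex-set analysis and propagation-metric target ranking.

Feedback loops sustain the disease phenotype in the influence graph, so
node sets intersecting every directed cycle (feedback vertex sets, FVS)
are candidate control points.  Two-node FVS are enumerated among the
cycle-participating nodes and ranked by the agreement of three network
propagation measures:

* PRINCE propagation — iterative smoothing ``F <- alpha * W' F +
  (1 - alpha) * Y`` on the underlying undirected graph with symmetric
  degree normalization, seeded at the pair;
* modified PRINCE — the same iteration on the directed, sign-aware graph
  with out-degree normalization (scores aggregated by absolute value);
* CheiRank — PageRank on the edge-reversed graph, scoring nodes by their
  outgoing influence.

A pair's final rank is the mean of its per-metric dense ranks among the
pairs appearing in the top fraction of all three metrics (the
"intersection"); remaining pairs are ranked below by the same mean.
Druggable pairs (both members ligands, receptors or transcription factors)
can be filtered for clinically actionable candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "cycle_nodes",
    "is_fvs",
    "enumerate_fvs_pairs",
    "prince_scores",
    "modified_prince_scores",
    "cheirank_scores",
    "rank_pairs",
    "filter_druggable",
    "FVSRanking",
]


def _simple_digraph(g) -> nx.DiGraph:
    """Collapse a multigraph to a simple DiGraph (structure only)."""
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes(data=True))
    h.add_edges_from((u, v) for u, v in g.edges())
    return h


def cycle_nodes(g) -> set:
    """Nodes lying on at least one directed cycle.

    These are the members of nontrivial strongly connected components,
    plus any self-loop node.
    """
    h = _simple_digraph(g)
    out = set()
    for comp in nx.strongly_connected_components(h):
        if len(comp) > 1:
            out |= comp
    out |= {u for u, v in h.edges() if u == v}
    return out


def is_fvs(g, node_set) -> bool:
    """True iff removing ``node_set`` leaves the graph acyclic."""
    h = _simple_digraph(g)
    h.remove_nodes_from(node_set)
    return nx.is_directed_acyclic_graph(h)


def enumerate_fvs_pairs(g, exclude=None) -> list[tuple]:
    """All unordered pairs of cycle nodes whose joint removal breaks every
    cycle, in deterministic lexicographic order."""
    cyc = cycle_nodes(g)
    if exclude:
        cyc -= set(exclude)
    pairs = []
    for u, v in combinations(sorted(cyc), 2):
        if is_fvs(g, {u, v}):
            pairs.append((u, v))
    return pairs


# --------------------------------------------------------------------------
# propagation metrics
# --------------------------------------------------------------------------


def _node_order(g) -> list:
    return sorted(g.nodes())


def prince_scores(
    g, seeds, alpha: float = 0.85, tol: float = 1e-9, max_iter: int = 10_000
) -> dict:
    """PRINCE propagation from a seed set on the underlying undirected graph.

    Iterates ``F <- alpha * W' F + (1 - alpha) * Y`` to a fixed point,
    where ``W' = D^{-1/2} A D^{-1/2}`` is the symmetrically normalized
    adjacency of the undirected structure and ``Y`` the seed indicator.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    order = _node_order(g)
    idx = {n: i for i, n in enumerate(order)}
    for s in seeds:
        if s not in idx:
            raise ValueError(f"seed {s!r} is not in the graph")
    n = len(order)
    A = np.zeros((n, n))
    for u, v in _simple_digraph(g).edges():
        A[idx[u], idx[v]] = 1.0
        A[idx[v], idx[u]] = 1.0
    deg = A.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    W = dinv[:, None] * A * dinv[None, :]
    Y = np.zeros(n)
    for s in seeds:
        Y[idx[s]] = 1.0
    F = (1.0 - alpha) * Y
    for _ in range(max_iter):
        F_new = alpha * (W @ F) + (1.0 - alpha) * Y
        if np.abs(F_new - F).max() < tol:
            return dict(zip(order, F_new))
        F = F_new
    raise RuntimeError(f"PRINCE iteration did not converge in {max_iter} steps")


def modified_prince_scores(
    g, seeds, alpha: float = 0.85, tol: float = 1e-9, max_iter: int = 10_000
) -> dict:
    """Directed, sign-aware PRINCE variant with out-degree normalization.

    Mass flows along edge direction: ``F_v <- alpha * sum_{u->v}
    sign(u,v)/outdeg(u) * F_u + (1-alpha) * Y_v``.  Scores can be negative
    through inhibiting edges; ranking aggregates their magnitudes.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    order = _node_order(g)
    idx = {n: i for i, n in enumerate(order)}
    for s in seeds:
        if s not in idx:
            raise ValueError(f"seed {s!r} is not in the graph")
    n = len(order)
    S = np.zeros((n, n))  # S[v, u] = sum of signs of u->v edges
    outdeg = np.zeros(n)
    for u, v, data in g.edges(data=True):
        S[idx[v], idx[u]] += data.get("sign", 1)
        outdeg[idx[u]] += 1.0
    M = S / np.where(outdeg > 0, outdeg, 1.0)[None, :]
    Y = np.zeros(n)
    for s in seeds:
        Y[idx[s]] = 1.0
    F = (1.0 - alpha) * Y
    for _ in range(max_iter):
        F_new = alpha * (M @ F) + (1.0 - alpha) * Y
        if np.abs(F_new - F).max() < tol:
            return dict(zip(order, F_new))
        F = F_new
    raise RuntimeError(f"modified PRINCE iteration did not converge in {max_iter} steps")


def cheirank_scores(g, damping: float = 0.85) -> dict:
    """CheiRank: PageRank on the edge-reversed graph (outgoing influence).

    Scores sum to 1.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    h = _simple_digraph(g).reverse()
    return nx.pagerank(h, alpha=damping)


# --------------------------------------------------------------------------
# ranking
# --------------------------------------------------------------------------


@dataclass
class FVSRanking:
    """Ranked two-node FVS candidates with per-metric scores and ranks."""

    table: pd.DataFrame
    alpha: float
    damping: float
    top_fraction: float

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.table.head(k)


_METRICS = ("prince", "modified_prince", "cheirank")


def rank_pairs(
    g,
    pairs,
    alpha: float = 0.85,
    damping: float = 0.85,
    top_fraction: float = 0.2,
    tol: float = 1e-9,
) -> FVSRanking:
    """Score and rank candidate pairs by the three propagation metrics.

    Per pair: total pair-seeded PRINCE score, total |modified PRINCE|
    score, and the sum of the two members' CheiRank.  Pairs in the top
    ``top_fraction`` of all three metrics form the intersection and are
    ranked first by the mean of their per-metric dense ranks; the rest
    follow by the same mean.  Ties break lexicographically on the pair.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no candidate pairs to rank")
    cheir = cheirank_scores(g, damping)
    records = []
    for u, v in pairs:
        pr = prince_scores(g, (u, v), alpha=alpha, tol=tol)
        mp = modified_prince_scores(g, (u, v), alpha=alpha, tol=tol)
        records.append(
            {
                "node_a": u,
                "node_b": v,
                "prince": sum(pr.values()),
                "modified_prince": sum(abs(x) for x in mp.values()),
                "cheirank": cheir[u] + cheir[v],
            }
        )
    df = pd.DataFrame(records)
    drugs = nx.get_node_attributes(g, "druggable")
    df["druggable"] = [
        bool(drugs.get(a, True)) and bool(drugs.get(b, True))
        for a, b in zip(df["node_a"], df["node_b"])
    ]
    for m in _METRICS:
        df[f"rank_{m}"] = df[m].rank(method="dense", ascending=False).astype(int)
        cutoff = df[m].quantile(1.0 - top_fraction)
        df[f"top_{m}"] = df[m] >= cutoff
    df["in_intersection"] = df[[f"top_{m}" for m in _METRICS]].all(axis=1)
    df["mean_rank"] = df[[f"rank_{m}" for m in _METRICS]].mean(axis=1)
    df = df.sort_values(
        by=["in_intersection", "mean_rank", "node_a", "node_b"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["final_rank"] = np.arange(1, len(df) + 1)
    return FVSRanking(table=df, alpha=alpha, damping=damping, top_fraction=top_fraction)


def filter_druggable(pairs, annotations) -> tuple[list[tuple], dict]:
    """Keep pairs whose both members are druggable.

    ``annotations`` maps node -> node_class (or node -> bool).  Returns the
    filtered pairs plus an audit of both counting conventions: the number
    of pairs containing at least one non-druggable member and the number
    with both members druggable.
    """
    druggable_classes = {"ligand", "receptor", "transcription_factor"}

    def is_druggable(node) -> bool:
        try:
            v = annotations[node]
        except (KeyError, TypeError):
            raise ValueError(f"node {node!r} has no annotation") from None
        if isinstance(v, bool):
            return v
        return v in druggable_classes

    kept, dropped = [], 0
    for u, v in pairs:
        if is_druggable(u) and is_druggable(v):
            kept.append((u, v))
        else:
            dropped += 1
    audit = {
        "n_pairs": len(pairs),
        "n_with_nondruggable": dropped,
        "n_both_druggable": len(kept),
    }
    return kept, audit
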