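"""Activation/influence graph of a model and its topology summaries.

Nodes are places.  A *transition* edge (u, v) records signal flow (some
transition u -> v); a *condition* edge (w, v) records regulatory
influence (w appears, positively or negatively, in the condition guarding
some transition into v).  Condition edges are unsigned in the topology —
the sign (activator/inhibitor) is kept as edge metadata.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
from networkx.algorithms import community

from .expressions import Not, Var
from .model import GuardedTransitionModel


def build_activation_graph(model: GuardedTransitionModel) -> nx.MultiDiGraph:
    """Directed multigraph with typed edges; one condition edge per
    (literal place, target) pair regardless of how many guards repeat it."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(model.places)
    seen_trans: set[tuple[str, str]] = set()
    cond_signs: dict[tuple[str, str], set[str]] = {}
    for tr in model.transitions:
        if (tr.source, tr.target) not in seen_trans:
            seen_trans.add((tr.source, tr.target))
            g.add_edge(tr.source, tr.target, key="transition", etype="transition")
        for node in tr.condition.walk():
            if isinstance(node, Var):
                cond_signs.setdefault((node.name, tr.target), set()).add("+")
            elif isinstance(node, Not) and isinstance(node.child, Var):
                cond_signs.setdefault((node.child.name, tr.target), set()).add("-")
        # places tested inside `when` guards influence the target too
        for name in sorted(tr.event.condition_places()):
            cond_signs.setdefault((name, tr.target), set()).add("+")
    for (w, v), signs in cond_signs.items():
        g.add_edge(w, v, key="condition", etype="condition", sign="".join(sorted(signs)))
    return g


def components(graph: nx.MultiDiGraph) -> list[set[str]]:
    """Weakly connected components, largest first."""
    comps = [set(c) for c in nx.weakly_connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def degree_distribution(graph: nx.MultiDiGraph) -> dict[int, int]:
    """Histogram of total degree (in + out, typed edges counted once each)."""
    return dict(sorted(Counter(d for _, d in graph.degree()).items()))


def modularity_clusters(
    graph: nx.MultiDiGraph, seed: int = 0
) -> tuple[list[set[str]], float]:
    """Greedy agglomerative modularity clustering on the undirected
    projection; returns the partition and its Newman modularity Q.

    The greedy merge is deterministic; ``seed`` is accepted for interface
    stability with randomized partitioners.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    und = nx.Graph()
    und.add_nodes_from(graph.nodes)
    und.add_edges_from((u, v) for u, v, _ in graph.edges(keys=True) if u != v)
    if und.number_of_edges() == 0:
        parts = [ {n} for n in sorted(und.nodes) ]
        return parts, 0.0
    comms = community.greedy_modularity_communities(und)
    parts = [set(c) for c in comms]
    q = community.modularity(und, parts)
    return parts, q


def to_graphml(graph: nx.MultiDiGraph) -> str:
    import io

    buf = io.BytesIO()
    nx.write_graphml(graph, buf)
    return buf.getvalue().decode()


def to_edge_tsv(graph: nx.MultiDiGraph) -> str:
    lines = ["source\ttarget\ttype\tsign"]
    for u, v, key, data in sorted(graph.edges(keys=True, data=True)):
        lines.append(f"{u}\t{v}\t{data.get('etype', key)}\t{data.get('sign', '')}")
    return "\n".join(lines) + "\n"
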