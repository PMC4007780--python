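"""Downstream analytics over enumerated trajectories.

The unit of analysis is the *activated-set* of a trajectory: the set of
places that ever became True while a scenario played out.  Trajectories
are tabulated as a binary occurrence matrix (rows = trajectories, columns
= places, 1 = activated), clustered hierarchically on Euclidean row
distances, and classified by Smad content: a gene is *smad-only* when
every one of its trajectories contains a Smad place, *non-smad* when none
does, and *mixed* otherwise.  Stimuli-combination extraction answers which
sets of extracellular inputs jointly initialize a gene's minimal
scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .model import GuardedTransitionModel, Scenario, Trajectory

DEFAULT_SMAD_PATTERNS = ("SMAD2", "SMAD3", "SMAD4")


@dataclass
class GeneRegulationRecord:
    """Everything the screen learned about one gene place."""

    gene: str
    scenarios: list[Scenario]
    trajectories: list[frozenset[str]]  # activated-sets of distinct trajectories
    error: str | None = None
    smad_class: str | None = None

    def frontier_sets(self) -> list[frozenset[str]]:
        return [s.frontier for s in self.scenarios]


def occurrence_matrix(
    trajectories: Sequence[Trajectory | frozenset | set],
    place_universe: Sequence[str],
) -> pd.DataFrame:
    """0/1 matrix: rows = trajectories, columns = places, 1 = activated."""
    cols = list(place_universe)
    rows = []
    for t in trajectories:
        activated = t.activated if isinstance(t, Trajectory) else frozenset(t)
        rows.append([1 if p in activated else 0 for p in cols])
    data = np.array(rows, dtype=int).reshape(len(rows), len(cols))
    return pd.DataFrame(data, columns=cols, index=range(len(rows)))


def cluster_trajectories(
    matrix: pd.DataFrame,
    linkage: str = "average",
    n_clusters: int | None = None,
):
    """Hierarchical agglomerative clustering on Euclidean row distances.

    Returns ``(Z, labels)`` — the scipy linkage matrix and, when
    ``n_clusters`` is given, flat cluster labels (1-based).  scipy's
    linkage is deterministic; exact distance ties are resolved by row
    index order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 trajectories")
    dist = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    z = hierarchy.linkage(dist, method=linkage)
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return z, labels


def dendrogram_newick(z: np.ndarray, leaf_names: Sequence[str] | None = None) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(z)
    names = list(leaf_names) if leaf_names else None

    def render(node, parent_dist) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            name = names[node.id] if names else f"t{node.id}"
            return f"{name}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"


def classify_smad(
    record: GeneRegulationRecord,
    patterns: Iterable[str] = DEFAULT_SMAD_PATTERNS,
) -> str:
    """smad-only / non-smad / mixed by Smad content of the trajectories."""
    patterns = tuple(patterns)
    if not patterns:
        raise ValueError("need at least one Smad name pattern")
    if not record.trajectories:
        raise ValueError(f"gene {record.gene!r} has no trajectories to classify")

    def has_smad(activated: frozenset[str]) -> bool:
        return any(any(pat in place for pat in patterns) for place in activated)

    flags = [has_smad(t) for t in record.trajectories]
    if all(flags):
        cls = "smad-only"
    elif not any(flags):
        cls = "non-smad"
    else:
        cls = "mixed"
    record.smad_class = cls
    return cls


def stimuli_combinations(
    records: dict[str, GeneRegulationRecord],
    stimuli: Iterable[str],
    anchor: str,
) -> tuple[dict[str, list[frozenset[str]]], dict[frozenset[str], list[str]]]:
    """Stimulus sets co-initializing each gene with the anchor stimulus.

    For each gene, the distinct sets ``frontier ∩ stimuli`` over its
    minimal scenarios that contain the anchor; plus the reverse map
    combination -> genes (the bipartite gene/stimuli structure).
    """
    stimuli = frozenset(stimuli)
    if anchor not in stimuli:
        raise ValueError(f"anchor {anchor!r} must be one of the stimuli")
    per_gene: dict[str, list[frozenset[str]]] = {}
    reverse: dict[frozenset[str], list[str]] = {}
    for gene in sorted(records):
        rec = records[gene]
        combos: list[frozenset[str]] = []
        for f in rec.frontier_sets():
            combo = frozenset(f & stimuli)
            if anchor in combo and combo not in combos:
                combos.append(combo)
        per_gene[gene] = sorted(combos, key=lambda c: (len(c), sorted(c)))
        for combo in combos:
            reverse.setdefault(combo, [])
            if gene not in reverse[combo]:
                reverse[combo].append(gene)
    return per_gene, reverse


def combinations_table(per_gene: dict[str, list[frozenset[str]]]) -> pd.DataFrame:
    """Long-format gene/stimuli-combination table (one row per pair)."""
    rows = [
        {"gene": gene, "combination": "+".join(sorted(combo)), "size": len(combo)}
        for gene, combos in sorted(per_gene.items())
        for combo in combos
    ]
    return pd.DataFrame(rows, columns=["gene", "combination", "size"])


def shared_trajectory_graph(
    model: GuardedTransitionModel,
    record_a: GeneRegulationRecord,
    record_b: GeneRegulationRecord,
):
    """Union of the two genes' activated subgraphs with origin labels.

    Nodes are the places activated by either gene's trajectories, labelled
    ``common`` / ``A-only`` / ``B-only``; edges are the activation-graph
    edges (transition and condition) restricted to those places.
    """
    from .graph_analysis import build_activation_graph

    if not record_a.trajectories or not record_b.trajectories:
        raise ValueError("both records must have at least one trajectory")
    act_a: set[str] = set().union(*record_a.trajectories)
    act_b: set[str] = set().union(*record_b.trajectories)
    keep = act_a | act_b
    g = build_activation_graph(model).subgraph(keep).copy()
    for n in g.nodes:
        if n in act_a and n in act_b:
            g.nodes[n]["origin"] = "common"
        elif n in act_a:
            g.nodes[n]["origin"] = "A-only"
        else:
            g.nodes[n]["origin"] = "B-only"
    return g


def shares_trajectory(
    record_a: GeneRegulationRecord, record_b: GeneRegulationRecord
) -> bool:
    """True when some trajectory pair overlaps in activated places, the two
    gene places themselves excluded."""
    exclude = {record_a.gene, record_b.gene}
    for ta in record_a.trajectories:
        a = ta - exclude
        for tb in record_b.trajectories:
            if a & (tb - exclude):
                return True
    return False
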