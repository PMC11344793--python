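"""Agglomerative conditional clustering of co-occurring taxa.

Each clustering run starts from one node per genus and repeatedly merges a
significantly associated pair (i, j) into a new node k that lives only in the
samples where both members occur: ``X_k = X_i * X_j`` and ``pi_k = pi_i *
pi_j``.  The samples where only one member occurred are handed to residual
nodes i* and j* (``X_i* = X_i * (1 - X_j)``, ``pi_i* = pi_i * (1 - pi_j)``),
which stay in play and may join *different* partners later — this is what
captures conditional associations, where a taxon pairs with one partner in
one habitat subset and another elsewhere.

Pair selection is stochastic (probability proportional to the aggregation
Z-score among eligible pairs), so many independent runs are combined into a
consensus network in which node and edge support counts how many runs
reproduced each assemblage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvariantError
from .io_model import OccurrenceTable
from .null_model import (
    ProbabilityMatrix,
    ScoreCalibration,
    pair_survival_batch,
    scores_from_survival,
)

__all__ = [
    "Node",
    "AssemblyNetwork",
    "CombinedNetwork",
    "merge_pair",
    "cluster_environment",
    "run_ensemble",
    "combine_runs",
    "consensus_terminals",
]


@dataclass
class Node:
    """One network node: a taxa set together with its presence and null
    probability vectors over the environment's samples."""

    node_id: int
    taxa: frozenset[str]
    presence: np.ndarray
    prob: np.ndarray
    is_residual: bool = False

    @property
    def occupancy(self) -> int:
        return int(self.presence.sum())


@dataclass
class AssemblyNetwork:
    """Directed agglomeration graph from a single clustering run."""

    environment: str
    run_seed: int
    sample_ids: list[str]
    nodes: dict[int, Node] = field(default_factory=dict)
    edges: list[tuple[int, int]] = field(default_factory=list)

    def taxa_sets(self) -> set[frozenset[str]]:
        return {nd.taxa for nd in self.nodes.values()}

    def edge_taxa(self) -> set[tuple[frozenset[str], frozenset[str]]]:
        return {
            (self.nodes[p].taxa, self.nodes[c].taxa) for p, c in self.edges
        }

    def assemblages(self) -> set[frozenset[str]]:
        """Multi-genus taxa sets present in this run."""
        return {t for t in self.taxa_sets() if len(t) >= 2}


def merge_pair(i: Node, j: Node, id_start: int = 0) -> tuple[Node, Node, Node]:
    """Merge two nodes into their joint-presence node plus two residuals.

    Returns ``(k, i_residual, j_residual)``.  The three presence vectors
    partition the parents' supports: ``X_k + X_i* = X_i`` and
    ``X_k + X_j* = X_j`` elementwise.
    """
    joint = i.presence * j.presence
    if not joint.any():
        raise InvariantError(
            f"non-co-occurring merge: nodes {i.node_id} and {j.node_id} share no samples"
        )
    k = Node(id_start, i.taxa | j.taxa, joint, i.prob * j.prob)
    i_res = Node(
        id_start + 1, i.taxa, i.presence * (1 - j.presence), i.prob * (1 - j.prob),
        is_residual=True,
    )
    j_res = Node(
        id_start + 2, j.taxa, j.presence * (1 - i.presence), j.prob * (1 - i.prob),
        is_residual=True,
    )
    return k, i_res, j_res


def _pair_stats(
    nodes_u: Sequence[Node],
    nodes_v: Sequence[Node],
    calibration: ScoreCalibration,
    min_cooccurrence: int,
) -> dict[frozenset[int], tuple[int, float]]:
    """Aggregation Z-scores for all (u, v) cross pairs whose co-occurrence
    count makes them potentially eligible.  Keys are id pairs; values
    ``(N, z)``."""
    cand = []
    seen: set[frozenset[int]] = set()
    for u in nodes_u:
        for v in nodes_v:
            if u.node_id == v.node_id:
                continue
            key = frozenset((u.node_id, v.node_id))
            if key in seen:
                continue
            seen.add(key)
            N = int((u.presence & v.presence).sum())
            if N > min_cooccurrence:
                cand.append((u, v, N))
    if not cand:
        return {}
    P_u = np.stack([u.prob for u, _, _ in cand])
    P_v = np.stack([v.prob for _, v, _ in cand])
    N = np.array([n for _, _, n in cand])
    sf = pair_survival_batch(P_u, P_v)
    S = scores_from_survival(sf, N)
    n_u = np.array([u.occupancy for u, _, _ in cand], dtype=float)
    n_v = np.array([v.occupancy for _, v, _ in cand], dtype=float)
    z = calibration.zscore(S, n_u, n_v)
    return {
        frozenset((u.node_id, v.node_id)): (int(Nk), float(zk))
        for (u, v, _), Nk, zk in zip(cand, N, z)
    }


def cluster_environment(
    table: OccurrenceTable,
    pi: ProbabilityMatrix,
    calibration: ScoreCalibration,
    seed: int | np.random.Generator = 0,
    min_cooccurrence: int = 5,
    environment: str = "",
    initial_stats: dict[frozenset[int], tuple[int, float]] | None = None,
) -> AssemblyNetwork:
    """One stochastic agglomeration run over an environment's samples.

    While there are pairs of nodes that are significantly associated (Z above
    the calibrated cutoff) and co-occur in more than ``min_cooccurrence``
    samples, one such pair is chosen at random with probability proportional
    to its Z-score and merged; scores involving the new and residual nodes
    are then recomputed from the updated presence/probability vectors.
    Residual nodes left with no samples are dropped.

    ``initial_stats`` lets callers precompute the (deterministic) genus-level
    pair statistics once and share them across runs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    run_seed = -1 if isinstance(seed, np.random.Generator) else int(seed)
    net = AssemblyNetwork(environment, run_seed, list(table.sample_ids))
    counter = itertools.count()
    active: dict[int, Node] = {}
    for g, genus in enumerate(table.genus_ids):
        node = Node(next(counter), frozenset([genus]), table.X[g].copy(), pi.pi[g].copy())
        net.nodes[node.node_id] = node
        active[node.node_id] = node

    if initial_stats is None:
        stats = _pair_stats(
            list(active.values()), list(active.values()), calibration, min_cooccurrence
        )
    else:
        stats = dict(initial_stats)

    cutoff = calibration.z_cutoff
    while True:
        elig = [(key, z) for key, (N, z) in stats.items() if z > cutoff]
        if not elig:
            break
        weights = np.array([max(z, 1e-12) for _, z in elig])
        pick = rng.choice(len(elig), p=weights / weights.sum())
        ia, ib = sorted(elig[pick][0])
        ni, nj = active[ia], active[ib]
        k, i_res, j_res = merge_pair(ni, nj, id_start=next(counter))
        next(counter), next(counter)  # reserve the residual ids

        del active[ia], active[ib]
        stats = {key: val for key, val in stats.items() if ia not in key and ib not in key}

        new_nodes = [k]
        for res in (i_res, j_res):
            if res.presence.any():
                new_nodes.append(res)
        for nd in new_nodes:
            net.nodes[nd.node_id] = nd
        net.edges.append((ia, k.node_id))
        net.edges.append((ib, k.node_id))

        stats.update(
            _pair_stats(new_nodes, list(active.values()) + new_nodes, calibration, min_cooccurrence)
        )
        for nd in new_nodes:
            active[nd.node_id] = nd
    return net


def run_ensemble(
    table: OccurrenceTable,
    pi: ProbabilityMatrix,
    calibration: ScoreCalibration,
    n_runs: int = 100,
    base_seed: int = 0,
    min_cooccurrence: int = 5,
    environment: str = "",
) -> list[AssemblyNetwork]:
    """``n_runs`` independent clustering runs with seeds spawned from
    ``base_seed``; results are reproducible bit-for-bit for a fixed seed."""
    if n_runs < 1:
        raise InvariantError("n_runs must be >= 1")
    genus_nodes = [
        Node(g, frozenset([genus]), table.X[g], pi.pi[g])
        for g, genus in enumerate(table.genus_ids)
    ]
    initial = _pair_stats(genus_nodes, genus_nodes, calibration, min_cooccurrence)
    out = []
    for child in np.random.SeedSequence(base_seed).spawn(n_runs):
        rng = np.random.default_rng(child)
        out.append(
            cluster_environment(
                table,
                pi,
                calibration,
                seed=rng,
                min_cooccurrence=min_cooccurrence,
                environment=environment,
                initial_stats=initial,
            )
        )
    return out


@dataclass
class CombinedNetwork:
    """Consensus of many clustering runs, keyed by taxa set.

    ``support`` counts, over all individual run networks, how many contained
    a node (or edge) with the same taxa content.
    """

    node_support: dict[frozenset[str], int]
    node_environments: dict[frozenset[str], set[str]]
    edge_support: dict[tuple[frozenset[str], frozenset[str]], int]
    n_networks: int
    min_support: int

    def multi_environment(self, key: frozenset[str]) -> bool:
        return len(self.node_environments.get(key, ())) > 1 and len(key) >= 2

    def assemblages(self) -> list[frozenset[str]]:
        return [k for k in self.node_support if len(k) >= 2]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for key, sup in self.node_support.items():
            g.add_node(
                "|".join(sorted(key)),
                taxa="|".join(sorted(key)),
                size=len(key),
                support=sup,
                environments="|".join(sorted(self.node_environments[key])),
                multi_environment=self.multi_environment(key),
            )
        for (p, c), sup in self.edge_support.items():
            g.add_edge("|".join(sorted(p)), "|".join(sorted(c)), support=sup)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_tsv(cls, nodes_path, edges_path) -> "CombinedNetwork":
        import pandas as pd

        nodes = pd.read_csv(nodes_path, sep="\t", dtype={"taxa": str})
        edges = pd.read_csv(edges_path, sep="\t", dtype={"parent": str, "child": str})
        node_support = {
            frozenset(r.taxa.split("|")): int(r.support) for r in nodes.itertuples()
        }
        node_envs = {
            frozenset(r.taxa.split("|")): set(str(r.environments).split("|"))
            for r in nodes.itertuples()
        }
        edge_support = {
            (frozenset(r.parent.split("|")), frozenset(r.child.split("|"))): int(r.support)
            for r in edges.itertuples()
        }
        min_sup = min(
            [*node_support.values(), *edge_support.values()], default=0
        )
        return cls(node_support, node_envs, edge_support,
                   n_networks=max(node_support.values(), default=0), min_support=min_sup)

    def write_tsv(self, nodes_path, edges_path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                (
                    "|".join(sorted(k)),
                    len(k),
                    sup,
                    "|".join(sorted(self.node_environments[k])),
                    self.multi_environment(k),
                )
                for k, sup in sorted(self.node_support.items(), key=lambda kv: -kv[1])
            ],
            columns=["taxa", "size", "support", "environments", "multi_environment"],
        ).to_csv(nodes_path, sep="\t", index=False)
        pd.DataFrame(
            [
                ("|".join(sorted(p)), "|".join(sorted(c)), sup)
                for (p, c), sup in sorted(self.edge_support.items(), key=lambda kv: -kv[1])
            ],
            columns=["parent", "child", "support"],
        ).to_csv(edges_path, sep="\t", index=False)


def combine_runs(
    runs: Mapping[str, Sequence[AssemblyNetwork]] | Sequence[AssemblyNetwork],
    min_support: int = 10,
) -> CombinedNetwork:
    """Collapse per-run networks into a consensus network.

    Nodes with identical taxa sets are collapsed (a residual node collapses
    with its source taxon); supports are counted over all individual
    networks; nodes are annotated with the environments whose runs produced
    them; nodes and edges with support below ``min_support`` are discarded.
    """
    if not isinstance(runs, Mapping):
        grouped: dict[str, list[AssemblyNetwork]] = {}
        for net in runs:
            grouped.setdefault(net.environment, []).append(net)
        runs = grouped
    node_support: dict[frozenset[str], int] = {}
    node_envs: dict[frozenset[str], set[str]] = {}
    edge_support: dict[tuple[frozenset[str], frozenset[str]], int] = {}
    n_networks = 0
    for env, nets in runs.items():
        for net in nets:
            n_networks += 1
            for key in net.taxa_sets():
                node_support[key] = node_support.get(key, 0) + 1
                node_envs.setdefault(key, set()).add(env)
            for ekey in net.edge_taxa():
                edge_support[ekey] = edge_support.get(ekey, 0) + 1
    nodes = {k: s for k, s in node_support.items() if s >= min_support}
    edges = {
        (p, c): s
        for (p, c), s in edge_support.items()
        if s >= min_support and p in nodes and c in nodes
    }
    return CombinedNetwork(
        node_support=nodes,
        node_environments={k: node_envs[k] for k in nodes},
        edge_support=edges,
        n_networks=n_networks,
        min_support=min_support,
    )


def consensus_terminals(
    net: CombinedNetwork, min_edge_support: int = 70
) -> set[frozenset[str]]:
    """Terminal assemblages of the highly supported consensus subnetwork.

    Keep only edges with support strictly above ``min_edge_support``; return
    the multi-genus nodes with no outgoing edge to a larger assemblage in
    that restricted graph."""
    strong_out: set[frozenset[str]] = {
        p for (p, c), s in net.edge_support.items() if s > min_edge_support
    }
    return {
        k for k in net.node_support if len(k) >= 2 and k not in strong_out
    }
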