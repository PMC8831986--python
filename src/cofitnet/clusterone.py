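"""Cohesiveness-based greedy detection of overlapping network modules.

A candidate module V is scored by its cohesiveness

    f(V) = w_in / (w_in + w_bound + p * |V|),

where w_in is the total edge weight inside V, w_bound the total weight of
edges crossing the boundary, and p a per-vertex penalty modelling unseen
connections.  Clusters are grown greedily from seed vertices by
best-improvement local search (add an adjacent external vertex or remove an
internal one, whichever single move raises f the most), highly overlapping
clusters are merged, and small or sparse clusters are discarded.

Unlike the original randomized variant, seeds are taken in descending
weighted-degree order (ties lexicographic), which makes the whole procedure
deterministic; a seeded random order is available via ``seed_order``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["Cluster", "ModuleSet", "cohesiveness", "grow_cluster", "detect_modules"]


@dataclass
class Cluster:
    members: frozenset[str]
    cohesiveness: float
    seed: str

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    """Modules surviving merge and filter, numbered CID-01... by size."""

    clusters: list[Cluster]

    def as_dict(self) -> dict[str, set[str]]:
        return {
            f"CID-{i:02d}": set(c.members)
            for i, c in enumerate(self.clusters, start=1)
        }

    def __len__(self) -> int:
        return len(self.clusters)


def _weights(net: nx.Graph, V: set[str]) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for u, v, w in net.edges(data="weight", default=1.0):
        inside = (u in V) + (v in V)
        if inside == 2:
            w_in += w
        elif inside == 1:
            w_bound += w
    return w_in, w_bound


def cohesiveness(net: nx.Graph, V: set[str], p: float = 2.0) -> float:
    """f(V) = w_in / (w_in + w_bound + p|V|); in [0, 1]."""
    if not V:
        raise ValueError("cohesiveness of an empty vertex set is undefined")
    missing = V - set(net.nodes)
    if missing:
        raise KeyError(f"vertices not in graph: {sorted(missing)[:5]}")
    w_in, w_bound = _weights(net, V)
    denom = w_in + w_bound + p * len(V)
    return w_in / denom if denom > 0 else 0.0


def grow_cluster(net: nx.Graph, seed: str, p: float = 2.0) -> Cluster:
    """Best-improvement local search from a seed vertex.

    At each step every external vertex adjacent to V (addition) and every
    internal vertex except the seed (removal) is evaluated; the single move
    with the largest strict gain in cohesiveness is applied.  Ties prefer
    additions over removals, then the lexicographically smallest gene.
    """
    if seed not in net:
        raise KeyError(f"seed gene {seed!r} is not in the graph")
    V: set[str] = {seed}
    # conn[v]: total weight between v and V, maintained incrementally
    conn: dict[str, float] = {}
    for nbr, data in net[seed].items():
        conn[nbr] = conn.get(nbr, 0.0) + data.get("weight", 1.0)
    w_in, w_bound = 0.0, sum(conn.values())

    def f(wi: float, wb: float, size: int) -> float:
        denom = wi + wb + p * size
        return wi / denom if denom > 0 else 0.0

    current = f(w_in, w_bound, len(V))
    while True:
        best = None  # (gain, move_rank, gene, new_w_in, new_w_bound)
        # additions: external vertices adjacent to V
        for v in sorted(cv for cv in conn if cv not in V):
            strength = conn[v]
            deg_w = sum(d.get("weight", 1.0) for d in net[v].values())
            wi = w_in + strength
            wb = w_bound - strength + (deg_w - strength)
            gain = f(wi, wb, len(V) + 1) - current
            cand = (gain, 0, v, wi, wb)
            if best is None or _better(cand, best):
                best = cand
        # removals: internal vertices, never the seed
        for v in sorted(V - {seed}):
            strength = conn.get(v, 0.0)  # weight v -> rest of V
            deg_w = sum(d.get("weight", 1.0) for d in net[v].values())
            wi = w_in - strength
            wb = w_bound + strength - (deg_w - strength)
            gain = f(wi, wb, len(V) - 1) - current
            cand = (gain, 1, v, wi, wb)
            if best is None or _better(cand, best):
                best = cand
        if best is None or best[0] <= 1e-12:
            break
        _, move, v, w_in, w_bound = best
        if move == 0:
            V.add(v)
            for nbr, data in net[v].items():
                conn[nbr] = conn.get(nbr, 0.0) + data.get("weight", 1.0)
        else:
            V.remove(v)
            for nbr, data in net[v].items():
                conn[nbr] = conn.get(nbr, 0.0) - data.get("weight", 1.0)
        current = f(w_in, w_bound, len(V))
    return Cluster(members=frozenset(V), cohesiveness=current, seed=seed)


def _better(cand: tuple, best: tuple) -> bool:
    """Larger gain wins; ties: additions before removals, then smaller gene."""
    return (-cand[0], cand[1], cand[2]) < (-best[0], best[1], best[2])


def overlap_score(a: frozenset[str], b: frozenset[str]) -> float:
    """omega(A, B) = |A∩B|^2 / (|A||B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _internal_density(net: nx.Graph, V: frozenset[str]) -> float:
    n = len(V)
    if n < 2:
        return 0.0
    edges = sum(1 for u, v in net.subgraph(V).edges)
    return edges / (n * (n - 1) / 2)


def _merge_to_fixpoint(
    clusters: list[frozenset[str]],
    merge_overlap: float,
    seeds: dict[frozenset[str], str] | None = None,
) -> list[frozenset[str]]:
    """Union cluster pairs with overlap score >= threshold until none remain."""
    clusters = list(clusters)
    changed = True
    while changed:
        changed = False
        clusters.sort(key=lambda m: tuple(sorted(m)))
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if overlap_score(clusters[i], clusters[j]) >= merge_overlap:
                    merged = clusters[i] | clusters[j]
                    if seeds is not None:
                        seeds[merged] = min(
                            seeds.get(clusters[i], ""), seeds.get(clusters[j], "")
                        )
                    clusters = [
                        m for k, m in enumerate(clusters) if k not in (i, j)
                    ] + [merged]
                    changed = True
                    break
            if changed:
                break
    return clusters


def seed_order(net: nx.Graph, seed: int | None = None) -> list[str]:
    """Seed vertices: descending weighted degree, ties lexicographic.

    With ``seed`` given, a seeded random shuffle instead (the original
    algorithm's randomized flavor).
    """
    nodes = sorted(net.nodes)
    if seed is not None:
        rng = np.random.default_rng(seed)
        return [nodes[i] for i in rng.permutation(len(nodes))]
    wdeg = {
        v: sum(d.get("weight", 1.0) for d in net[v].values()) for v in nodes
    }
    return sorted(nodes, key=lambda v: (-wdeg[v], v))


def detect_modules(
    net: nx.Graph,
    p: float = 2.0,
    min_size: int = 3,
    min_density: float = 0.5,
    merge_overlap: float = 0.8,
    random_seed: int | None = None,
) -> ModuleSet:
    """Grow, merge and filter cohesive clusters into a ModuleSet.

    Seeds are visited in ``seed_order``; a vertex already inside a grown
    cluster is skipped as a seed.  Cluster pairs with overlap score
    >= ``merge_overlap`` are merged (union, cohesiveness recomputed) to a
    fixpoint, then clusters below ``min_size`` or internal edge density
    below ``min_density`` are dropped.  Surviving modules are numbered
    CID-01... in descending size (ties: lexicographic member tuple).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty graph")
    covered: set[str] = set()
    grown: list[Cluster] = []
    for s in seed_order(net, random_seed):
        if s in covered:
            continue
        c = grow_cluster(net, s, p=p)
        grown.append(c)
        covered |= c.members

    seeds = {c.members: c.seed for c in grown}
    clusters = _merge_to_fixpoint([c.members for c in grown], merge_overlap, seeds)

    final = []
    for members in clusters:
        if len(members) < min_size:
            continue
        if _internal_density(net, members) < min_density:
            continue
        final.append(
            Cluster(
                members=members,
                cohesiveness=cohesiveness(net, set(members), p=p),
                seed=seeds.get(members, min(members)),
            )
        )
    final.sort(key=lambda c: (-len(c.members), tuple(sorted(c.members))))
    return ModuleSet(final)
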