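"""Leiden community detection with the constant Potts model (CPM) quality.

The algorithm follows the move–refine–aggregate scheme: a fast local-moving
phase greedily improves CPM quality, a refinement phase splits each
community into well-connected sub-communities (with randomness governed by
the exploration parameter ``theta``), and the refined partition is
aggregated into a smaller graph on which the process repeats. Refinement is
what distinguishes Leiden from Louvain and guarantees that every returned
community is connected.

CPM quality of a partition P of a weighted graph:

    H(P) = sum over communities c of [ w_in(c) - gamma * s_c * (s_c - 1) / 2 ]

where ``w_in(c)`` is the total internal edge weight and ``s_c`` the number
of original vertices in c. A community survives only if its internal weight
density exceeds ``gamma``; unlike modularity, CPM is resolution-consistent
and has no preferred community size.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np

Edge = tuple[int, int, float]


class _Graph:
    """Adjacency-list weighted graph with vertex sizes and self-weights."""

    def __init__(self, n: int, edges: Sequence[Edge], sizes=None, self_w=None):
        self.n = n
        self.adj: list[dict[int, float]] = [dict() for _ in range(n)]
        for u, v, w in edges:
            if u == v:
                continue
            self.adj[u][v] = self.adj[u].get(v, 0.0) + w
            self.adj[v][u] = self.adj[v].get(u, 0.0) + w
        self.sizes = list(sizes) if sizes is not None else [1] * n
        # internal weight already collapsed inside an aggregated vertex
        self.self_w = list(self_w) if self_w is not None else [0.0] * n


def cpm_quality(
    n_nodes: int,
    edges: Sequence[Edge],
    membership: Sequence[int],
    gamma: float,
) -> float:
    """CPM quality of a flat partition of the given edge list."""
    w_in: dict[int, float] = {}
    size: dict[int, int] = {}
    for v in range(n_nodes):
        c = membership[v]
        size[c] = size.get(c, 0) + 1
    for u, v, w in edges:
        if membership[u] == membership[v]:
            c = membership[u]
            w_in[c] = w_in.get(c, 0.0) + w
    return sum(
        w_in.get(c, 0.0) - gamma * s * (s - 1) / 2.0 for c, s in size.items()
    )


def _local_move(g: _Graph, memb: list[int], gamma: float, rng) -> list[int]:
    """Fast local moving: greedy single-vertex CPM moves with a work queue."""
    comm_size: dict[int, int] = {}
    for v in range(g.n):
        comm_size[memb[v]] = comm_size.get(memb[v], 0) + g.sizes[v]
    order = rng.permutation(g.n)
    queue = deque(int(v) for v in order)
    in_queue = [True] * g.n
    free_labels: list[int] = []
    next_label = max(memb, default=-1) + 1
    while queue:
        v = queue.popleft()
        in_queue[v] = False
        c = memb[v]
        sv = g.sizes[v]
        w_to: dict[int, float] = {}
        for u, w in g.adj[v].items():
            w_to[memb[u]] = w_to.get(memb[u], 0.0) + w
        leave_gain = -w_to.get(c, 0.0) + gamma * sv * (comm_size[c] - sv)
        best_comm, best_delta = c, 0.0
        for d in sorted(w_to):
            if d == c:
                continue
            delta = leave_gain + w_to[d] - gamma * sv * comm_size[d]
            if delta > best_delta + 1e-12:
                best_comm, best_delta = d, delta
        # moving out into a fresh singleton community
        if leave_gain > best_delta + 1e-12 and comm_size[c] > sv:
            if free_labels:
                best_comm = min(free_labels)
            else:
                best_comm = next_label
            best_delta = leave_gain
        if best_comm != c:
            if best_comm == next_label:
                next_label += 1
            elif best_comm in free_labels:
                free_labels.remove(best_comm)
            memb[v] = best_comm
            comm_size[c] -= sv
            comm_size[best_comm] = comm_size.get(best_comm, 0) + sv
            if comm_size[c] == 0:
                del comm_size[c]
                free_labels.append(c)
            for u in g.adj[v]:
                if memb[u] != best_comm and not in_queue[u]:
                    queue.append(u)
                    in_queue[u] = True
    return memb


def _refine(
    g: _Graph, memb: list[int], gamma: float, theta: float, rng
) -> list[int]:
    """Split each community into well-connected sub-communities.

    Each vertex starts as its own refined community; a vertex still alone
    may merge into a well-connected refined community inside its parent
    community, sampled with probability proportional to exp(delta_H / theta)
    over the non-degrading candidates. Small theta is near-greedy; larger
    theta explores more.
    """
    refined = list(range(g.n))
    members: dict[int, list[int]] = {c: [] for c in set(memb)}
    for v in range(g.n):
        members[memb[v]].append(v)

    for c, nodes in sorted(members.items()):
        if len(nodes) == 1:
            continue
        size_s = sum(g.sizes[v] for v in nodes)
        node_set = set(nodes)
        # per refined community inside S: vertex size and connectivity to S \ C
        r_size = {v: g.sizes[v] for v in nodes}
        r_conn = {
            v: sum(w for u, w in g.adj[v].items() if u in node_set)
            for v in nodes
        }
        r_members = {v: [v] for v in nodes}
        singleton = {v: True for v in nodes}

        for v in [nodes[i] for i in rng.permutation(len(nodes))]:
            if not singleton[v]:
                continue
            sv = g.sizes[v]
            if r_conn[v] < gamma * sv * (size_s - sv):
                continue  # v itself not well connected within S
            w_to: dict[int, float] = {}
            for u, w in g.adj[v].items():
                if u in node_set and refined[u] != refined[v]:
                    w_to[refined[u]] = w_to.get(refined[u], 0.0) + w
            cands, deltas = [], []
            for rc in sorted(w_to):
                src = r_size[rc]
                if r_conn[rc] < gamma * src * (size_s - src):
                    continue  # target sub-community not well connected
                delta = w_to[rc] - gamma * sv * src
                if delta >= -1e-12:
                    cands.append(rc)
                    deltas.append(max(delta, 0.0))
            if not cands:
                continue
            if theta > 0:
                logits = np.asarray(deltas) / theta
                probs = np.exp(logits - logits.max())
                probs /= probs.sum()
                choice = int(rng.choice(len(cands), p=probs))
            else:
                choice = int(np.argmax(deltas))
            target = cands[choice]
            old = refined[v]
            refined[v] = target
            singleton[v] = False
            singleton[target] = False
            r_members[target].append(v)
            r_size[target] += sv
            # connectivity of merged community to S \ C
            r_conn[target] += r_conn[old] - 2.0 * w_to[target]
            del r_size[old], r_conn[old], r_members[old]
    return refined


def _aggregate(
    g: _Graph, refined: list[int], memb: list[int]
) -> tuple[_Graph, list[int], list[int]]:
    """Collapse refined communities into vertices of a smaller graph."""
    labels = sorted(set(refined))
    compact = {lab: i for i, lab in enumerate(labels)}
    node_of = [compact[refined[v]] for v in range(g.n)]
    m = len(labels)
    sizes = [0] * m
    self_w = [0.0] * m
    agg_edges: dict[tuple[int, int], float] = {}
    for v in range(g.n):
        sizes[node_of[v]] += g.sizes[v]
        self_w[node_of[v]] += g.self_w[v]
    for v in range(g.n):
        for u, w in g.adj[v].items():
            if u < v:
                continue
            a, b = node_of[v], node_of[u]
            if a == b:
                self_w[a] += w
            else:
                key = (min(a, b), max(a, b))
                agg_edges[key] = agg_edges.get(key, 0.0) + w
    edges = [(a, b, w) for (a, b), w in sorted(agg_edges.items())]
    agg = _Graph(m, edges, sizes=sizes, self_w=self_w)
    # aggregated vertex inherits the parent community of its members
    init = [0] * m
    for v in range(g.n):
        init[node_of[v]] = memb[v]
    return agg, node_of, init


def leiden_cpm(
    n_nodes: int,
    edges: Sequence[Edge],
    gamma: float,
    theta: float = 0.01,
    n_iterations: int = 10,
    seed: int = 0,
) -> list[int]:
    """Partition a weighted graph by Leiden/CPM; returns a membership list.

    ``n_iterations`` repeats the full move–refine–aggregate cycle, each
    starting from the previous partition; quality is non-decreasing across
    iterations. Labels are compacted to 0..k-1 in order of smallest member.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if n_nodes == 0:
        return []
    rng = np.random.default_rng(seed)
    membership = list(range(n_nodes))
    base = _Graph(n_nodes, edges)
    for _ in range(n_iterations):
        membership = _one_cycle(base, membership, gamma, theta, rng)
    return _canonical(membership)


def _one_cycle(base: _Graph, membership: list[int], gamma, theta, rng) -> list[int]:
    g = base
    memb = list(membership)
    node_map = list(range(base.n))  # original vertex -> current-level vertex
    while True:
        memb = _local_move(g, memb, gamma, rng)
        if len(set(memb)) == g.n:
            break
        refined = _refine(g, memb, gamma, theta, rng)
        agg, node_of, init = _aggregate(g, refined, memb)
        if agg.n == g.n:
            break
        node_map = [node_of[node_map[v]] for v in range(base.n)]
        g, memb = agg, init
    return [memb[node_map[v]] for v in range(base.n)]


def _canonical(membership: Sequence[int]) -> list[int]:
    seen: dict[int, int] = {}
    out = []
    for c in membership:
        if c not in seen:
            seen[c] = len(seen)
        out.append(seen[c])
    return out
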