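"""Median-joining haplotype networks for binary (0/1) haplotype data.

The network starts from the observed haplotypes and iteratively augments them
with median (Steiner) vectors: for triplets of nodes that are mutually close
under the minimum-spanning criterion, the per-site majority consensus is a
candidate unsampled intermediate.  Medians are added greedily while they
shorten the total network length (the minimum-spanning-tree weight over the
current node set); obsolete medians (degree <= 2 in the feasible-link graph,
which for binary Hamming data never shorten any connection) are pruned, so
surviving medians always have degree >= 3.  Feasible links are pairs whose
direct distance does not exceed the minimax path distance (the largest edge
on the minimum-spanning-tree path) by more than ``epsilon``; epsilon = 0
reproduces the minimum spanning network.  All tie-breaks are lexicographic,
so the result is invariant under permutation of the input haplotypes.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = ["build_mj_network", "export_dot"]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mst_and_length(nodes: list[str]) -> tuple[nx.Graph, float]:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            g.add_edge(u, v, weight=_hamming(u, v))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return mst, float(mst.size(weight="weight"))


def _minimax_distances(mst: nx.Graph, nodes: list[str]) -> dict[tuple[str, str], int]:
    """Largest edge weight on the (unique) MST path between each node pair;
    identical for every MST, hence deterministic."""
    out: dict[tuple[str, str], int] = {}
    for src in nodes:
        best = {src: 0}
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            for v in mst.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    best[v] = max(best[u], mst.edges[u, v]["weight"])
                    stack.append(v)
        for v, w in best.items():
            out[(src, v)] = w
    return out


def _feasible_links(nodes: list[str], epsilon: float) -> set[tuple[str, str]]:
    mst, _ = _mst_and_length(nodes)
    mm = _minimax_distances(mst, nodes)
    links = set()
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if _hamming(u, v) <= mm[(u, v)] + epsilon:
                links.add((u, v))
    return links


def _median(u: str, v: str, w: str) -> str:
    return "".join("1" if (a + b + c).count("1") >= 2 else "0"
                   for a, b, c in zip(u, v, w))


def build_mj_network(
    haplotypes,
    frequencies=None,
    epsilon: float = 0,
    metadata: dict | None = None,
    max_rounds: int = 100,
) -> nx.Graph:
    """Construct a median-joining network.

    Parameters
    ----------
    haplotypes : iterable of equal-length 0/1 strings (>= 2 distinct).
    frequencies : optional map haplotype -> frequency/count, attached to nodes.
    epsilon : link-feasibility tolerance (0 = NETWORK's default).
    metadata : optional map haplotype -> dict of extra node attributes
        (e.g. star label, population); passed through to the export.

    Returns a :class:`networkx.Graph` whose nodes are haplotype strings with
    attributes ``frequency``, ``is_median`` and any metadata; edge attribute
    ``weight`` is the number of differing sites.
    """
    observed = sorted(set(haplotypes))
    if len(observed) < 2:
        raise ValueError("need at least 2 distinct haplotypes")
    L = len(observed[0])
    if any(len(h) != L for h in observed):
        raise ValueError("haplotypes must have equal length")
    if any(set(h) - {"0", "1"} for h in observed):
        raise ValueError("haplotypes must be 0/1 strings")

    nodes = list(observed)
    _, length = _mst_and_length(nodes)
    for _ in range(max_rounds):
        links = _feasible_links(nodes, epsilon)
        adj: dict[str, list[str]] = {u: [] for u in nodes}
        for u, v in links:
            adj[u].append(v)
            adj[v].append(u)
        candidates = set()
        for u in nodes:
            nbrs = sorted(adj[u])
            for i, v in enumerate(nbrs):
                for w in nbrs[i + 1:]:
                    m = _median(u, v, w)
                    if m not in nodes:
                        candidates.add(m)
        best_m, best_len = None, length
        for m in sorted(candidates):
            _, new_len = _mst_and_length(nodes + [m])
            if new_len < best_len - 1e-9 or (
                best_m is not None and new_len == best_len and m < best_m
            ):
                best_m, best_len = m, new_len
        if best_m is None:
            break
        # total network length never increases when a median is added
        assert best_len <= length + 1e-9
        nodes = sorted(nodes + [best_m])
        length = best_len

    # prune obsolete medians: degree <= 2 never shortens a connection on
    # binary Hamming data (triangle equality)
    while True:
        links = _feasible_links(nodes, epsilon)
        deg = {u: 0 for u in nodes}
        for u, v in links:
            deg[u] += 1
            deg[v] += 1
        drop = [u for u in nodes if u not in observed and deg[u] <= 2]
        if not drop:
            break
        nodes = [u for u in nodes if u not in set(drop)]

    g = nx.Graph(epsilon=epsilon)
    freq = dict(frequencies) if frequencies is not None else {}
    meta = metadata or {}
    for u in nodes:
        g.add_node(u, frequency=float(freq.get(u, 0.0)),
                   is_median=u not in observed, **meta.get(u, {}))
    for u, v in _feasible_links(nodes, epsilon):
        g.add_edge(u, v, weight=_hamming(u, v))
    return g


def export_dot(g: nx.Graph, path) -> None:
    """Write a Graphviz DOT rendering of the network (median vectors as
    point-shaped black nodes, node size scaled by frequency)."""
    with open(path, "w") as fh:
        fh.write("graph haplonet {\n  node [shape=circle];\n")
        for u, d in sorted(g.nodes(data=True)):
            attrs = []
            if d.get("is_median"):
                attrs.append('shape=point, style=filled, fillcolor=black, label=""')
            else:
                label = d.get("star", u)
                size = 0.3 + 2.0 * float(d.get("frequency", 0.0))
                attrs.append(f'label="{label}", width={size:.2f}')
            fh.write(f'  "{u}" [{", ".join(attrs)}];\n')
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f'  "{u}" -- "{v}" [label="{int(d["weight"])}"];\n')
        fh.write("}\n")
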