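"""Independent brute-force oracles shared by the test modules.

Everything here recomputes quantities by exhaustive enumeration or explicit
two-pass arithmetic, never by calling the implementation under test.
"""

import networkx as nx
import numpy as np


def enumerate_shortest_paths(graph: nx.Graph, lengths: dict) -> dict:
    """All-pairs shortest-path data by exhaustive simple-path enumeration.

    ``lengths`` maps sorted node pairs to edge lengths.  For each unordered
    pair the minimum total length is found over *all* simple paths; the
    single counted path is then reconstructed backwards, at each step taking
    the smallest-index neighbour that lies on some minimal route (the same
    lexicographic convention the implementation documents).

    Returns dict with 'dist' {(s,t): length}, 'usage' {edge: count},
    'visits' {node: intermediate count}.
    """
    nodes = sorted(graph.nodes)
    usage = {tuple(sorted(e)): 0 for e in graph.edges}
    visits = {v: 0 for v in nodes}
    dist = {}
    for si, s in enumerate(nodes):
        for t in nodes[si + 1 :]:
            best = np.inf
            for p in nx.all_simple_paths(graph, s, t):
                total = sum(
                    lengths[tuple(sorted((a, b)))] for a, b in zip(p, p[1:])
                )
                best = min(best, total)
            if np.isfinite(best):
                dist[(s, t)] = best
    for si, s in enumerate(nodes):
        d = {s: 0.0}
        for t in nodes:
            if t != s and (min(s, t), max(s, t)) in dist:
                d[t] = dist[(min(s, t), max(s, t))]
        for t in nodes[si + 1 :]:
            if t not in d:
                continue
            node, path = t, [t]
            while node != s:
                cands = [
                    u
                    for u in graph[node]
                    if u in d
                    and abs(d[u] + lengths[tuple(sorted((u, node)))] - d[node]) <= 1e-9
                ]
                node = min(cands)
                path.append(node)
            for a, b in zip(path, path[1:]):
                usage[tuple(sorted((a, b)))] += 1
            for v in path[1:-1]:
                visits[v] += 1
    return {"dist": dist, "usage": usage, "visits": visits}


def two_pass_mean_sem(samples: np.ndarray) -> tuple[float, float]:
    """Mean and SEM by explicit two-pass arithmetic over the first axis."""
    w = len(samples)
    mean = sum(samples) / w
    if w < 2:
        return float(mean), float("nan")
    var = sum((x - mean) ** 2 for x in samples) / (w - 1)
    return float(mean), float(np.sqrt(var) / np.sqrt(w))


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> nx.Graph:
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g
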