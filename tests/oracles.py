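"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive (exhaustive enumeration) and share no code with
the implementations they check.
"""

from itertools import permutations

import numpy as np


def brute_force_metrics(nodes, edges, focal):
    """Degree, strength, normalized betweenness by exhaustive path enumeration.

    ``edges``: {(a, b): weight}.  Distances are 1/weight; for every ordered
    node arrangement we enumerate all simple paths between each pair, find
    the minimum total distance, count minimal paths, and accumulate the
    fraction passing through the focal node.  Normalization divides by
    (n-1)(n-2)/2 (undirected pairs excluding the focal).
    """
    nodes = list(nodes)
    adj = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w
    degree = len(adj.get(focal, {}))
    strength = sum(adj.get(focal, {}).values())

    n = len(nodes)
    if n < 3:
        return degree, strength, 0.0
    accum = 0.0
    others = [v for v in nodes if v != focal]
    for i, s in enumerate(others):
        for t in others[i + 1:]:
            paths = _all_simple_paths(adj, s, t, nodes)
            if not paths:
                continue
            dists = [sum(1.0 / adj[u][v] for u, v in zip(p, p[1:])) for p in paths]
            dmin = min(dists)
            minimal = [p for p, d in zip(paths, dists) if np.isclose(d, dmin, atol=1e-12)]
            through = sum(focal in p[1:-1] for p in minimal)
            accum += through / len(minimal)
    norm = (n - 1) * (n - 2) / 2
    return degree, strength, accum / norm


def _all_simple_paths(adj, s, t, nodes):
    """All simple s-t paths by checking every permutation of intermediates."""
    inter = [v for v in nodes if v not in (s, t)]
    paths = []
    for r in range(len(inter) + 1):
        for mid in permutations(inter, r):
            path = (s, *mid, t)
            if all(v in adj.get(u, {}) for u, v in zip(path, path[1:])):
                paths.append(path)
    return paths


def random_small_graph(rng, max_nodes=6):
    """Random weighted graph with integer reciprocal weights (exact distances)."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.6:
                k = int(rng.integers(1, 9))
                edges[(nodes[i], nodes[j])] = 1.0 / k  # distance = k exactly
    return nodes, edges
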