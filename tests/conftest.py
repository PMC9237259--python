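import itertools

import numpy as np
import pandas as pd
import pytest

from fosnet import CohortMatrix, load_reference_summary


@pytest.fixture(scope="session")
def reference_summary():
    return load_reference_summary()


@pytest.fixture()
def small_cohort(reference_summary):
    """Deterministic 24-animal cohort (6/group) with uncorrelated marginals."""
    from fosnet import generate_cohort

    return generate_cohort(reference_summary, n_per_group=6, seed=11)


def make_cohort_from_activity(activity: np.ndarray, regions, group="Naive",
                              groups=("Naive", "MPTP", "Acu", "Sham")):
    """Wrap an (animals x regions) array as a single-group CohortMatrix."""
    df = pd.DataFrame(activity, columns=list(regions))
    df.insert(0, "group", group)
    df.index = [f"a{i}" for i in range(len(df))]
    df.index.name = "animal_id"
    return CohortMatrix(data=df, regions=list(regions), groups=list(groups))


def brute_force_betweenness(nodes, edges):
    """Exhaustive all-pairs shortest-path betweenness (node and edge).

    Enumerates every shortest path between every unordered node pair by
    breadth-first layering plus recursive backtracking; each pair
    contributes fractionally across its shortest paths. Independent of any
    graph library.
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        dist = {s: 0}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def back(node, tail):
            if node == s:
                paths.append([s] + tail)
                return
            for w in adj[node]:
                if dist.get(w, -1) == dist[node] - 1:
                    back(w, [node] + tail)

        back(t, [])
        return paths

    node_btw = {n: 0.0 for n in nodes}
    edge_btw = {tuple(sorted(e)): 0.0 for e in edges}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        share = 1.0 / len(paths)
        for path in paths:
            for inner in path[1:-1]:
                node_btw[inner] += share
            for a, b in zip(path, path[1:]):
                edge_btw[tuple(sorted((a, b)))] += share
    return node_btw, edge_btw
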