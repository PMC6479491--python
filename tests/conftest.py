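import numpy as np
import pytest

import rinflow as rf


@pytest.fixture
def static_ensemble() -> rf.TrajectoryEnsemble:
    """5-residue chain, 6 identical frames (no fluctuations)."""
    return rf.generate_ensemble(
        rf.EnsembleSpec(n_residues=5, n_frames=6, fluctuation_profile=0.0,
                        seed=11))


@pytest.fixture
def noisy_ensemble() -> rf.TrajectoryEnsemble:
    return rf.generate_ensemble(
        rf.EnsembleSpec(n_residues=6, n_frames=20, fluctuation_profile=0.3,
                        seed=7))


@pytest.fixture
def hub_model() -> rf.StructureModel:
    """Two 4-residue clusters bridged by the hub at residue index 4."""
    return rf.generate_hub_structure(4, seed=3)


def random_graph_edges(n: int, p: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Erdos-Renyi edge list used by the graph-oracle tests."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if rng.random() < p]


def make_network(n: int, edge_list: list[tuple[int, int]]) -> rf.ResidueInteractionNetwork:
    """Wrap an abstract unit-weight graph in the RIN container."""
    from rinflow.rin_centrality import RINEdge, ResidueNode
    nodes = [ResidueNode(label=f"G{i + 1}", chain_id="A", residue_index=i,
                         backbone_center=np.array([float(i), 0.0, 0.0]),
                         sidechain_center=None)
             for i in range(n)]
    edges = [RINEdge(i=a, j=b, contact_types=frozenset({"backbone-backbone"}),
                     min_center_distance=1.0, hbond_count=0)
             for a, b in edge_list]
    return rf.ResidueInteractionNetwork(nodes=nodes, edges=edges)


def enumerate_shortest_paths(n: int, edge_list: list[tuple[int, int]],
                             s: int, t: int) -> list[tuple[int, ...]]:
    """All geodesics s->t by depth-limited DFS (independent of Brandes)."""
    adj = {i: set() for i in range(n)}
    for a, b in edge_list:
        adj[a].add(b)
        adj[b].add(a)
    # plain BFS for the geodesic length
    dist = {s: 0}
    frontier = [s]
    while frontier and t not in dist:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    if t not in dist:
        return []
    target_len = dist[t]
    paths: list[tuple[int, ...]] = []

    def dfs(path: list[int]) -> None:
        v = path[-1]
        if len(path) - 1 == target_len:
            if v == t:
                paths.append(tuple(path))
            return
        for w in adj[v]:
            if w not in path:
                path.append(w)
                dfs(path)
                path.pop()

    dfs([s])
    return paths


def brute_force_betweenness(n: int, edge_list: list[tuple[int, int]]) -> np.ndarray:
    """Normalized betweenness from explicit geodesic enumeration."""
    cb = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_shortest_paths(n, edge_list, s, t)
            if not paths:
                continue
            for k in range(n):
                if k in (s, t):
                    continue
                through = sum(1 for p in paths if k in p)
                cb[k] += through / len(paths)
    if n > 2:
        cb *= 2.0 / ((n - 1) * (n - 2))
    return cb


def brute_force_closeness(n: int, edge_list: list[tuple[int, int]]) -> np.ndarray:
    """Component-scaled closeness from plain BFS distances."""
    adj = {i: set() for i in range(n)}
    for a, b in edge_list:
        adj[a].add(b)
        adj[b].add(a)
    out = np.zeros(n)
    for k in range(n):
        dist = {k: 0}
        frontier = [k]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
            frontier = nxt
        r = len(dist)
        if r == 1:
            continue
        total = sum(dist.values())
        out[k] = ((total / (r - 1)) ** -1) * (r - 1) / (n - 1)
    return out
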