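"""Weighted residue interaction network (RIN) and centrality analysis.

Nodes are amino-acid residues, each carrying two coarse-grained centers:
the Calpha position (backbone) and the side-chain heavy atom farthest from
Calpha (absent for glycine).  An edge exists when any center-center
distance between two residues is below the contact cutoff (strict, default
7 A); the number of hydrogen bonds between the two residues is stored as
the edge weight.

Shortest paths use unit edge length by default — d(i,k) is the minimum
number of edges — because most contact edges carry zero H-bonds and the
closeness definition is stated in edge counts.  The stored H-bond weights
can enter the path metric through ``weights="inverse-hbond"``
(length 1/(1+hbond_count)) for sensitivity analysis.

Degree, closeness (Dijkstra) and betweenness (Brandes) centralities are
implemented here directly; normalized betweenness uses the
2/((N-1)(N-2)) constant and excludes path endpoints.
"""

from __future__ import annotations

import heapq
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbond import HBondCriterion, detect_hbonds
from .structure_io import (AtomSelection, BACKBONE_ATOM_NAMES, STANDARD_AA,
                           StructureModel, WATER_RESNAMES)

__all__ = [
    "ResidueNode",
    "RINEdge",
    "ResidueInteractionNetwork",
    "CentralityTable",
    "CentralityDiff",
    "build_rin",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "centrality_table",
    "threshold_report",
    "centrality_diff",
]

_EPS = 1e-12  # path-length equality tolerance for weighted shortest paths


@dataclass
class ResidueNode:
    label: str  # author-numbered, e.g. Y314
    chain_id: str
    residue_index: int
    backbone_center: np.ndarray  # Calpha position, A
    sidechain_center: np.ndarray | None  # farthest heavy atom from CA, A


@dataclass
class RINEdge:
    i: int  # node list indices, i < j
    j: int
    contact_types: frozenset[str]
    min_center_distance: float  # A
    hbond_count: int = 0


@dataclass
class ResidueInteractionNetwork:
    nodes: list[ResidueNode]
    edges: list[RINEdge]

    @property
    def n(self) -> int:
        return len(self.nodes)

    def adjacency(self, weights: str | None = None) -> list[list[tuple[int, float]]]:
        """Adjacency lists of (neighbor, edge length)."""
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n)]
        for e in self.edges:
            if weights is None:
                length = 1.0
            elif weights == "inverse-hbond":
                length = 1.0 / (1.0 + e.hbond_count)
            else:
                raise ValueError(f"unknown weights mode {weights!r}")
            adj[e.i].append((e.j, length))
            adj[e.j].append((e.i, length))
        return adj


# ---------------------------------------------------------------------------
# network construction

_SIDECHAIN_EXCLUDE = set(BACKBONE_ATOM_NAMES) | {"OXT"}

CONTACT_BB = "backbone-backbone"
CONTACT_BS = "backbone-sidechain"
CONTACT_SS = "sidechain-sidechain"


def build_rin(model: StructureModel, cutoff: float = 7.0,
              hbond_criterion: HBondCriterion = HBondCriterion(),
              exclude_neighbors: int = 0,
              include_ligand: bool = False) -> ResidueInteractionNetwork:
    """Build the residue interaction network of a single structure.

    ``exclude_neighbors=k`` drops edges between residues within k sequence
    positions on the same chain (default 0: sequence-adjacent residues are
    connected like any others).  ``include_ligand`` adds each non-water
    HETATM group as one node located at its heavy-atom centroid.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = model.coords
    nodes: list[ResidueNode] = []
    node_residue: list[int] = []
    skipped = 0
    for res in model.residues:
        if res.name in WATER_RESNAMES:
            continue
        if res.name not in STANDARD_AA:
            continue
        ca = [i for i in res.atom_indices if model.atoms[i].name == "CA"]
        if not ca:
            skipped += 1
            continue
        side = [i for i in res.atom_indices
                if model.atoms[i].element != "H"
                and model.atoms[i].name not in _SIDECHAIN_EXCLUDE]
        sc_center = None
        if side:
            d = np.linalg.norm(coords[side] - coords[ca[0]], axis=1)
            sc_center = coords[side[int(np.argmax(d))]].copy()
        nodes.append(ResidueNode(label=res.label, chain_id=res.chain_id,
                                 residue_index=res.index,
                                 backbone_center=coords[ca[0]].copy(),
                                 sidechain_center=sc_center))
        node_residue.append(res.index)
    if include_ligand:
        for res in model.residues:
            if res.hetero and res.name not in WATER_RESNAMES \
                    and res.name not in STANDARD_AA:
                heavy = [i for i in res.atom_indices
                         if model.atoms[i].element != "H"]
                if not heavy:
                    continue
                centroid = coords[heavy].mean(axis=0)
                nodes.append(ResidueNode(label=res.label, chain_id=res.chain_id,
                                         residue_index=res.index,
                                         backbone_center=centroid,
                                         sidechain_center=None))
                node_residue.append(res.index)
    if skipped:
        warnings.warn(f"{skipped} residue(s) without a CA atom excluded "
                      "from the network")

    hb_counts = _hbond_counts_by_residue_pair(model, coords, hbond_criterion)

    edges: list[RINEdge] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            ni, nj = nodes[i], nodes[j]
            if exclude_neighbors and ni.chain_id == nj.chain_id and \
                    abs(ni.residue_index - nj.residue_index) <= exclude_neighbors:
                continue
            types: set[str] = set()
            dmin = np.inf
            pairs = [(ni.backbone_center, nj.backbone_center, CONTACT_BB),
                     (ni.backbone_center, nj.sidechain_center, CONTACT_BS),
                     (ni.sidechain_center, nj.backbone_center, CONTACT_BS),
                     (ni.sidechain_center, nj.sidechain_center, CONTACT_SS)]
            for a, b, kind in pairs:
                if a is None or b is None:
                    continue
                d = float(np.linalg.norm(a - b))
                if d < cutoff:
                    types.add(kind)
                    dmin = min(dmin, d)
            if types:
                key = (min(ni.residue_index, nj.residue_index),
                       max(ni.residue_index, nj.residue_index))
                edges.append(RINEdge(i=i, j=j, contact_types=frozenset(types),
                                     min_center_distance=dmin,
                                     hbond_count=hb_counts.get(key, 0)))
    return ResidueInteractionNetwork(nodes=nodes, edges=edges)


def _hbond_counts_by_residue_pair(model: StructureModel, coords: np.ndarray,
                                  criterion: HBondCriterion) -> dict[tuple[int, int], int]:
    if not any(a.element == "H" for a in model.atoms):
        warnings.warn("structure has no explicit hydrogens; all edge H-bond "
                      "counts are 0")
        return {}
    everything = AtomSelection(indices=np.arange(model.n_atoms), label="all")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = detect_hbonds(model, coords, everything, everything, criterion)
    counts: dict[tuple[int, int], int] = {}
    for r in records:
        ri = model.atoms[r.donor].residue_index
        rj = model.atoms[r.acceptor].residue_index
        key = (min(ri, rj), max(ri, rj))
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# shortest paths


def _bfs_distances(adj: list[list[tuple[int, float]]], source: int) -> np.ndarray:
    n = len(adj)
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    q = deque([source])
    while q:
        v = q.popleft()
        for w, _ in adj[v]:
            if np.isinf(dist[w]):
                dist[w] = dist[v] + 1.0
                q.append(w)
    return dist


def _dijkstra_distances(adj: list[list[tuple[int, float]]], source: int) -> np.ndarray:
    n = len(adj)
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    done = np.zeros(n, dtype=bool)
    while heap:
        d, v = heapq.heappop(heap)
        if done[v]:
            continue
        done[v] = True
        for w, length in adj[v]:
            nd = d + length
            if nd < dist[w]:
                dist[w] = nd
                heapq.heappush(heap, (nd, w))
    return dist


# ---------------------------------------------------------------------------
# centralities


def degree_centrality(net: ResidueInteractionNetwork
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Raw degree per node and the degree/(N-1) normalized variant."""
    raw = np.zeros(net.n, dtype=int)
    for e in net.edges:
        raw[e.i] += 1
        raw[e.j] += 1
    norm = raw / (net.n - 1) if net.n > 1 else raw.astype(float)
    return raw, norm


def closeness_centrality(net: ResidueInteractionNetwork,
                         weights: str | None = None,
                         mode: str = "component-scaled") -> np.ndarray:
    """Closeness: reciprocal of the mean shortest-path distance to a node.

    On disconnected graphs the ``component-scaled`` mode averages over the
    node's component and scales by (reachable-1)/(N-1); ``strict`` mode
    requires a connected graph and applies the plain definition.
    """
    if net.n < 2:
        raise ValueError("closeness requires at least 2 nodes")
    adj = net.adjacency(weights)
    n = net.n
    out = np.zeros(n)
    singleton = 0
    for k in range(n):
        dist = _dijkstra_distances(adj, k)
        reachable = np.isfinite(dist)
        r = int(reachable.sum())  # includes k itself
        if r < n and mode == "strict":
            raise ValueError("graph is disconnected; strict closeness "
                             "requires a connected graph")
        if r == 1:
            singleton += 1
            out[k] = 0.0
            continue
        total = dist[reachable].sum()
        out[k] = ((total / (r - 1)) ** -1) * (r - 1) / (n - 1)
    if singleton:
        warnings.warn(f"{singleton} isolated node(s) assigned closeness 0")
    return out


def betweenness_centrality(net: ResidueInteractionNetwork,
                           weights: str | None = None,
                           normalized: bool = True) -> np.ndarray:
    """Betweenness via Brandes' single-source accumulation.

    Endpoints are excluded; the normalized value divides the raw pair sum
    by (N-1)(N-2)/2, giving values in [0, 1].
    """
    if net.n < 3:
        raise ValueError("betweenness requires at least 3 nodes")
    adj = net.adjacency(weights)
    n = net.n
    cb = np.zeros(n)
    for s in range(n):
        order, preds, sigma = _brandes_sssp(adj, s, weighted=weights is not None)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    cb /= 2.0  # each unordered pair accumulated from both endpoints
    if normalized:
        cb *= 2.0 / ((n - 1) * (n - 2))
    return cb


def _brandes_sssp(adj: list[list[tuple[int, float]]], s: int, weighted: bool
                  ) -> tuple[list[int], list[list[int]], np.ndarray]:
    """Single-source shortest-path DAG: visit order, predecessors, path counts."""
    n = len(adj)
    sigma = np.zeros(n)
    sigma[s] = 1.0
    preds: list[list[int]] = [[] for _ in range(n)]
    order: list[int] = []
    if not weighted:
        dist = np.full(n, -1.0)
        dist[s] = 0.0
        q = deque([s])
        while q:
            v = q.popleft()
            order.append(v)
            for w, _ in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1.0
                    q.append(w)
                if dist[w] == dist[v] + 1.0:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
    else:
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        seen = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if seen[v]:
                continue
            seen[v] = True
            order.append(v)
            for w, length in adj[v]:
                nd = d + length
                if nd < dist[w] - _EPS:
                    dist[w] = nd
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (nd, w))
                elif abs(nd - dist[w]) <= _EPS and not seen[w]:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
    return order, preds, sigma


# ---------------------------------------------------------------------------
# tables, thresholds, state differences


@dataclass
class CentralityTable:
    """Per-residue degree, closeness and betweenness centralities."""

    table: pd.DataFrame  # residue, chain, degree, c_d, c_c, c_b
    correlations: pd.DataFrame  # 3x3 Pearson matrix (NaN when degenerate)
    n_nodes: int


@dataclass
class CentralityDiff:
    """Per-residue |delta C_B| between two states with threshold flags."""

    table: pd.DataFrame  # residue, cb_a, cb_b, abs_diff, flags
    threshold: float
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)


def centrality_table(net: ResidueInteractionNetwork,
                     weights: str | None = None,
                     closeness_mode: str = "component-scaled") -> CentralityTable:
    """All three centralities plus their pairwise Pearson correlations."""
    raw_deg, c_d = degree_centrality(net)
    c_c = closeness_centrality(net, weights=weights, mode=closeness_mode)
    c_b = betweenness_centrality(net, weights=weights)
    table = pd.DataFrame({
        "residue": [nd.label for nd in net.nodes],
        "chain": [nd.chain_id for nd in net.nodes],
        "degree": raw_deg,
        "c_d": c_d,
        "c_c": c_c,
        "c_b": c_b,
    })
    cols = ["c_d", "c_c", "c_b"]
    corr = pd.DataFrame(np.full((3, 3), np.nan), index=cols, columns=cols)
    for a in range(3):
        for b in range(3):
            x = table[cols[a]].to_numpy()
            y = table[cols[b]].to_numpy()
            # degenerate (constant) distributions leave the correlation
            # undefined; guard with a relative spread tolerance
            if np.std(x) > 1e-12 * (1 + np.abs(x).max()) and \
                    np.std(y) > 1e-12 * (1 + np.abs(y).max()):
                corr.iloc[a, b] = float(np.corrcoef(x, y)[0, 1])
    return CentralityTable(table=table, correlations=corr, n_nodes=net.n)


def threshold_report(table: CentralityTable, cb_min: float = 0.05) -> pd.DataFrame:
    """Residues with C_B >= cb_min, sorted by descending C_B.

    The result's ``attrs["percentile"]`` records the empirical percentile
    of the threshold within the C_B distribution.
    """
    sel = table.table[table.table["c_b"] >= cb_min]
    out = sel.sort_values("c_b", ascending=False,
                          kind="stable").reset_index(drop=True)
    cb = table.table["c_b"].to_numpy()
    out.attrs["percentile"] = float(100.0 * np.mean(cb < cb_min))
    return out


def centrality_diff(table_a: CentralityTable, table_b: CentralityTable,
                    threshold: float = 0.02,
                    map_threshold: float = 0.03) -> CentralityDiff:
    """Absolute betweenness difference per residue between two states."""
    a = table_a.table.set_index(["residue", "chain"])
    b = table_b.table.set_index(["residue", "chain"])
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("states share no residues; cannot compare")
    unmatched_a = [f"{r}" for r, _ in a.index.difference(b.index)]
    unmatched_b = [f"{r}" for r, _ in b.index.difference(a.index)]
    diff = (a.loc[common, "c_b"] - b.loc[common, "c_b"]).abs()
    out = pd.DataFrame({
        "residue": [r for r, _ in common],
        "chain": [c for _, c in common],
        "cb_a": a.loc[common, "c_b"].to_numpy(),
        "cb_b": b.loc[common, "c_b"].to_numpy(),
        "abs_diff": diff.to_numpy(),
    })
    out[f"flag_{threshold:g}"] = out["abs_diff"] >= threshold
    out[f"flag_{map_threshold:g}"] = out["abs_diff"] >= map_threshold
    out = out.sort_values("abs_diff", ascending=False,
                          kind="stable").reset_index(drop=True)
    return CentralityDiff(table=out, threshold=threshold,
                          unmatched_a=unmatched_a, unmatched_b=unmatched_b)
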