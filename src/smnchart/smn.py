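"""Stable-matching neighbor (SMN) assignment and 3D layout.

Each cell acts simultaneously as a host and as a potential guest. One round
of Gale-Shapley deferred acceptance -- hosts propose down their affinity
row, guests hold the best offer by their affinity column, ties broken by
lower cell index -- produces a stable matching: no host-guest pair both
strictly prefer each other over their assigned partners. Rounds are run k
times (default 30); after each round the matched pairs' affinities are
removed (set to -inf in both orientations) so a pair can never rematch,
prioritizing still-unmatched cells. The undirected union of all matched
pairs is the SMN graph. Deferred acceptance makes at most c^2 proposals per
round, so the whole assignment is polynomial.

The graph is visualized by a 3-dimensional force-directed
Fruchterman-Reingold layout (seeded, hence reproducible); disconnected
graphs are laid out per component and the components translated apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class SMNGraph:
    """Simple undirected graph of stable-matching neighbor pairs."""

    node_ids: list[str]
    edges: set[frozenset]
    k_requested: int
    node_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.node_ids)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= node_set:
                raise ValueError(f"edge references unknown node: {set(e)}")

    @property
    def nodes(self) -> list[str]:
        return self.node_ids

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for e in self.edges:
            if node in e:
                (other,) = e - {node}
                out.append(other)
        return sorted(out)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def relabeled(self, mapping: dict[str, str]) -> "SMNGraph":
        return SMNGraph(
            node_ids=[mapping[n] for n in self.node_ids],
            edges={frozenset(mapping[n] for n in e) for e in self.edges},
            k_requested=self.k_requested,
            node_labels=(
                {mapping[n]: l for n, l in self.node_labels.items()}
                if self.node_labels
                else None
            ),
        )


@dataclass
class Layout3D:
    coords: np.ndarray  # cells x 3
    node_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.node_ids), 3):
            raise ValueError("coords must be one 3D row per node")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("layout coordinates must be finite")


def deferred_acceptance(
    utility: np.ndarray, exclude: set[tuple[int, int]] | None = None
) -> tuple[set[tuple[int, int]], int]:
    """One round of host-proposing deferred acceptance.

    Hosts propose in descending order of their utility row; each guest holds
    the offer with the highest utility in its own column; ties break toward
    the lower cell index. Excluded pairs (either orientation) and -inf
    utilities are never proposed. Returns (matching pairs, proposal count).
    A host with no admissible guest simply stays unmatched.
    """
    util = np.array(utility, dtype=float)
    c = util.shape[0]
    if util.shape != (c, c) or c < 2:
        raise ValueError("utility must be square with c >= 2")
    np.fill_diagonal(util, -np.inf)
    if exclude:
        for i, j in exclude:
            util[i, j] = -np.inf
            util[j, i] = -np.inf

    # preference lists: descending utility, ties by lower guest index
    idx = np.arange(c)
    prefs = np.empty((c, c), dtype=np.intp)
    for h in range(c):
        prefs[h] = np.lexsort((idx, -util[h]))

    next_prop = np.zeros(c, dtype=np.intp)  # next preference pointer per host
    guest_holder = np.full(c, -1, dtype=np.intp)
    free = list(range(c - 1, -1, -1))  # pop() yields ascending host index
    proposals = 0
    while free:
        h = free.pop()
        while next_prop[h] < c:
            g = prefs[h, next_prop[h]]
            next_prop[h] += 1
            if util[h, g] == -np.inf:
                next_prop[h] = c  # remaining prefs are also -inf
                break
            proposals += 1
            holder = guest_holder[g]
            if holder == -1:
                guest_holder[g] = h
                break
            # guest compares offers by its own utility column
            if util[h, g] > util[holder, g] or (
                util[h, g] == util[holder, g] and h < holder
            ):
                guest_holder[g] = h
                free.append(holder)
                break
            # rejected; keep proposing
    pairs = {(int(guest_holder[g]), int(g)) for g in range(c) if guest_holder[g] != -1}
    return pairs, proposals


def stable_match_round(
    utility: np.ndarray, exclude: set[tuple[int, int]] | None = None
) -> set[tuple[int, int]]:
    """Stable (host, guest) matching for one round; see `deferred_acceptance`."""
    pairs, _ = deferred_acceptance(utility, exclude)
    return pairs


def assign_smn_graph(
    A_hat: np.ndarray,
    k: int = 30,
    cell_ids: list[str] | None = None,
    annotations: dict[str, str] | None = None,
) -> SMNGraph:
    """Run k sequential matching rounds and collect the undirected SMN graph.

    After each round, matched pairs are removed from the utility (both
    orientations set to -inf) so they cannot rematch; duplicate undirected
    edges are therefore impossible by construction but still de-duplicated.
    Cells may end with fewer than k distinct neighbors once the matching
    pool is exhausted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    util = np.array(A_hat, dtype=float)
    c = util.shape[0]
    if c <= k:
        logger.warning("k = %d neighbors requested for only %d cells", k, c)
    np.fill_diagonal(util, -np.inf)
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(c)]
    if len(ids) != c:
        raise ValueError("cell_ids length must match the affinity matrix")

    edges: set[frozenset] = set()
    for round_no in range(k):
        pairs, _ = deferred_acceptance(util)
        if not pairs:
            logger.warning(
                "matching pool exhausted after %d of %d rounds", round_no, k
            )
            break
        for h, g in pairs:
            edges.add(frozenset((ids[h], ids[g])))
            util[h, g] = -np.inf
            util[g, h] = -np.inf
    labels = None
    if annotations is not None:
        labels = {i: annotations[i] for i in ids if i in annotations}
    return SMNGraph(node_ids=list(ids), edges=edges, k_requested=k, node_labels=labels)


def layout_3d(graph: SMNGraph, seed: int = 60611, iterations: int = 500) -> Layout3D:
    """Seeded 3D Fruchterman-Reingold layout of the SMN graph.

    A single node sits at the origin; disconnected graphs are laid out per
    component (with a warning) and the components translated apart along x.
    """
    if not graph.node_ids:
        raise ValueError("cannot lay out an empty graph")
    g = graph.to_networkx()
    if len(g) == 1:
        return Layout3D(
            coords=np.zeros((1, 3)), node_ids=list(graph.node_ids), seed=seed
        )
    components = [sorted(comp) for comp in nx.connected_components(g)]
    components.sort(key=lambda comp: comp[0])
    pos: dict[str, np.ndarray] = {}
    if len(components) > 1:
        logger.warning(
            "SMN graph has %d components; laying out separately", len(components)
        )
    x_offset = 0.0
    for comp in components:
        sub = g.subgraph(comp)
        if len(sub) == 1:
            sub_pos = {comp[0]: np.zeros(3)}
        else:
            sub_pos = nx.spring_layout(
                sub, dim=3, seed=seed, iterations=iterations, scale=1.0
            )
        xs = [p[0] for p in sub_pos.values()]
        width = max(xs) - min(xs) if xs else 0.0
        for n, p in sub_pos.items():
            q = np.asarray(p, dtype=float)
            q[0] += x_offset - min(xs)
            pos[n] = q
        x_offset += width + 3.0  # gap between components
    coords = np.vstack([pos[n] for n in graph.node_ids])
    return Layout3D(coords=coords, node_ids=list(graph.node_ids), seed=seed)
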