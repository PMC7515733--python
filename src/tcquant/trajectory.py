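"""Transition structure between clusters, trajectories, cell orderings and
pseudotime.

Each transition cell (TC) is attributed to the unordered pair of clusters
holding its two largest membership probabilities; tabulating these counts
gives a cluster-cluster transition graph whose edges connect neighboring
states.  A cluster with TC toward every other cluster is an intermediate
cell state (ICS) candidate.  Trajectories are simple paths from a chosen
initial cluster through the neighbor graph; each collects the cells resident
on it, is scored by the fraction of all cells it contains, and orders its
cells by membership and plasticity so that pseudotime (cumulative embedding
distance, per-segment rescaled) increases along the transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionGraph",
    "Trajectory",
    "build_transition_graph",
    "infer_trajectories",
    "align_cells",
    "pseudotime",
]


@dataclass
class TransitionGraph:
    tc_counts: np.ndarray  # k x k symmetric ints, zero diagonal
    tc_fraction: np.ndarray  # counts / n_cells
    neighbors: nx.Graph
    ics_candidates: list[int]
    n_cells: int


@dataclass
class Trajectory:
    cluster_path: list[int]
    cell_order: list[int]
    probability: float
    start_cell: int | None = None
    pseudotime: np.ndarray | None = None
    segment_of_cell: dict[int, int] = field(default_factory=dict)


def _top_two(P: np.ndarray) -> np.ndarray:
    """Per cell, the unordered pair of the two largest membership columns.

    Ties resolve toward the smaller cluster index (argsort is stable on the
    negated array).
    """
    order = np.argsort(-P, axis=1, kind="stable")
    return order[:, :2]


def build_transition_graph(P: np.ndarray, tc_mask: np.ndarray) -> TransitionGraph:
    """Tabulate TC counts per cluster pair and find ICS candidates."""
    P = np.asarray(P, dtype=float)
    tc_mask = np.asarray(tc_mask, dtype=bool)
    if P.shape[0] != tc_mask.shape[0]:
        raise ValueError("P and tc_mask disagree on the number of cells")
    n, k = P.shape
    counts = np.zeros((k, k), dtype=int)
    toptwo = _top_two(P)
    for i in np.flatnonzero(tc_mask):
        a, b = sorted(toptwo[i])
        counts[a, b] += 1
        counts[b, a] += 1
    G = nx.Graph()
    G.add_nodes_from(range(k))
    for a in range(k):
        for b in range(a + 1, k):
            if counts[a, b] > 0:
                G.add_edge(a, b, weight=int(counts[a, b]))
    ics = [
        c
        for c in range(k)
        if all(counts[c, j] > 0 for j in range(k) if j != c)
    ]
    if tc_mask.sum() == 0:
        logger.warning("no transition cells: transition graph is empty")
    return TransitionGraph(
        tc_counts=counts,
        tc_fraction=counts / n,
        neighbors=G,
        ics_candidates=ics,
        n_cells=n,
    )


def infer_trajectories(
    graph: TransitionGraph,
    initial_cluster: int,
    P: np.ndarray,
    tc_mask: np.ndarray,
    cpi: np.ndarray | None = None,
) -> list[Trajectory]:
    """Enumerate simple paths from the initial cluster and score them.

    A path collects the cells whose two top clusters are consecutive on it
    plus every cell whose argmax cluster lies on it; its occurrence
    probability is the collected fraction of all cells.  Paths come back
    sorted by descending probability, then by length, with branches explored
    in order of descending TC count for determinism.
    """
    P = np.asarray(P, dtype=float)
    n, k = P.shape
    G = graph.neighbors
    if initial_cluster not in G:
        raise ValueError(f"unknown cluster {initial_cluster}")
    argmax = np.argmax(P, axis=1)
    toptwo = _top_two(P)

    if G.degree(initial_cluster) == 0:
        logger.warning("initial cluster %d is isolated", initial_cluster)
        cells = np.flatnonzero(argmax == initial_cluster)
        return [
            Trajectory(
                cluster_path=[initial_cluster],
                cell_order=list(cells),
                probability=len(cells) / n,
            )
        ]

    paths: list[list[int]] = []

    def _extend(path: list[int]) -> None:
        tail = path[-1]
        nbrs = [v for v in G.neighbors(tail) if v not in path]
        nbrs.sort(key=lambda v: (-graph.tc_counts[tail, v], v))
        if len(path) >= 2:
            paths.append(list(path))
        for v in nbrs:
            if len(path) < k:
                _extend(path + [v])

    _extend([initial_cluster])

    out = []
    for path in paths:
        cells = _cells_on_path(path, argmax, toptwo)
        traj = Trajectory(
            cluster_path=path,
            cell_order=list(cells),
            probability=len(cells) / n,
        )
        if cpi is not None:
            order, seg_of = align_cells(P, cpi, path)
            traj.cell_order = order
            traj.segment_of_cell = seg_of
            traj.start_cell = int(np.argmax(P[:, path[0]]))
        out.append(traj)
    out.sort(key=lambda t: (-t.probability, -len(t.cluster_path), t.cluster_path))
    return out


def _cells_on_path(path: list[int], argmax: np.ndarray, toptwo: np.ndarray) -> np.ndarray:
    on_path = np.isin(argmax, path)
    edges = {frozenset(e) for e in zip(path[:-1], path[1:])}
    aligned = np.array(
        [frozenset(tt) in edges for tt in toptwo], dtype=bool
    )
    return np.flatnonzero(on_path | aligned)


def align_cells(
    P: np.ndarray,
    cpi: np.ndarray,
    cluster_path: list[int],
    start_cell: int | None = None,
) -> tuple[list[int], dict[int, int]]:
    """Order the path's cells along the transition.

    For each consecutive pair (a -> b): first the cells with argmax a in
    ascending CPI (leaving a means gaining plasticity), then the cells
    aligned between a and b with argmax b in descending CPI (arriving at b
    means losing it).  Cells already placed by an earlier segment are
    skipped; stragglers whose argmax is the final cluster close the ordering
    in descending CPI.  The start cell — the one with the largest membership
    in the initial cluster — is forced to the front.

    Returns the ordered cell ids and a map cell -> segment index used by the
    pseudotime rescaling.
    """
    P = np.asarray(P, dtype=float)
    cpi = np.asarray(cpi, dtype=float)
    argmax = np.argmax(P, axis=1)
    toptwo = _top_two(P)
    if start_cell is None:
        start_cell = int(np.argmax(P[:, cluster_path[0]]))

    order: list[int] = []
    seg_of: dict[int, int] = {}
    placed = np.zeros(P.shape[0], dtype=bool)

    def _place(cells: np.ndarray, seg: int) -> None:
        for c in cells:
            c = int(c)
            if not placed[c]:
                placed[c] = True
                seg_of[c] = seg
                order.append(c)

    pairs = list(zip(cluster_path[:-1], cluster_path[1:]))
    for seg, (a, b) in enumerate(pairs):
        leaving = np.flatnonzero(argmax == a)
        # ascending CPI, start cell first on the first segment
        key = cpi[leaving].copy()
        if seg == 0 and start_cell in leaving:
            key[np.flatnonzero(leaving == start_cell)[0]] = -np.inf
        _place(leaving[np.argsort(key, kind="stable")], seg)
        arriving = np.flatnonzero(
            (argmax == b)
            & (np.minimum(toptwo[:, 0], toptwo[:, 1]) == min(a, b))
            & (np.maximum(toptwo[:, 0], toptwo[:, 1]) == max(a, b))
        )
        _place(arriving[np.argsort(-cpi[arriving], kind="stable")], seg)
    if pairs:
        last_seg = len(pairs) - 1
        stragglers = np.flatnonzero(argmax == cluster_path[-1])
        _place(stragglers[np.argsort(-cpi[stragglers], kind="stable")], last_seg)
    else:  # single-cluster path
        cells = np.flatnonzero(argmax == cluster_path[0])
        _place(cells[np.argsort(cpi[cells], kind="stable")], 0)
    return order, seg_of


def pseudotime(
    coords: np.ndarray,
    trajectories: list[Trajectory],
    mode: str = "cumulative",
) -> np.ndarray:
    """Per-cell global pseudotime from the 2-D embedding.

    Within each trajectory the raw value is the cumulative embedding
    distance along the ordered cells from the start cell (``mode="direct"``
    uses straight-line distance to the start instead).  Values are min-max
    rescaled per segment to the window [s, s+1] so segment s is comparable
    across trajectories, and each cell keeps the minimum of its scaled
    values over all trajectories containing it.  Cells on no trajectory get
    NaN.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    global_pt = np.full(n, np.nan)
    for traj in trajectories:
        cells = traj.cell_order
        if not cells:
            continue
        xy = coords[cells]
        if mode == "cumulative":
            steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            raw = np.concatenate([[0.0], np.cumsum(steps)])
        elif mode == "direct":
            raw = np.linalg.norm(xy - xy[0], axis=1)
        else:
            raise ValueError(f"unknown pseudotime mode {mode!r}")
        segs = np.array([traj.segment_of_cell.get(c, 0) for c in cells])
        scaled = np.empty_like(raw)
        for s in np.unique(segs):
            m = segs == s
            lo, hi = raw[m].min(), raw[m].max()
            scaled[m] = s + (raw[m] - lo) / (hi - lo) if hi > lo else s
        traj.pseudotime = scaled
        for c, v in zip(cells, scaled):
            if np.isnan(global_pt[c]) or v < global_pt[c]:
                global_pt[c] = v
    return global_pt
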