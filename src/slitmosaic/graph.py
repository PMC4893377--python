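"""Global bundle adjustment of pairwise translations (graph-SLAM form).

Every accepted pairwise translation between frames i and j contributes two
linear constraints, one per axis:

    x_i - x_j = dx        y_i - y_j = dy

Stacking one row per constraint gives an over-determined sparse system
``A x = b`` whose least-squares solution distributes measurement error over
the whole graph instead of accumulating it along the frame order — this is
what removes the drift of sequential chaining.  ``A`` has a +1 in column i
and a -1 in column j of each row and is shared by both axes; x and y are
solved independently.

The translation gauge is fixed by pinning one anchor frame at the origin
(dropping its column); without this, ``A`` is rank-deficient because adding
a constant to all positions leaves every constraint satisfied.  Nodes not
connected to the anchor cannot be positioned and are reported as excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .register import PairwiseTranslation

__all__ = [
    "PoseGraph",
    "DriftReport",
    "build_system",
    "solve_positions",
    "drift_report",
    "write_positions_csv",
    "read_positions_csv",
]


@dataclass
class PoseGraph:
    """Assembled constraint system and (once solved) global positions."""

    n_nodes: int
    edges: list[PairwiseTranslation]
    A: sparse.csr_matrix  # (n_edges, n_nodes)
    b: np.ndarray  # (n_edges, 2), columns (bx, by)
    positions: np.ndarray | None = None  # (n_nodes, 2), NaN where unplaced
    placed: np.ndarray | None = None  # boolean (n_nodes,)


def build_system(
    edges: list[PairwiseTranslation],
    n_nodes: int | None = None,
    *,
    accepted_only: bool = True,
    weight_by_inliers: bool = False,
) -> PoseGraph:
    """Assemble the sparse constraint matrix from accepted edges.

    Each edge (i, j, delta) yields a row with ``A[row, i] = +1`` and
    ``A[row, j] = -1`` and right-hand side ``delta``; duplicate edges stay
    as separate rows (the redundancy is what makes the adjustment an
    over-determined least-squares problem).  With ``weight_by_inliers`` both
    sides of each row are scaled by ``sqrt(inliers)``, weighting confident
    edges more; by default all constraints count equally.
    """
    use = [e for e in edges if e.accepted or not accepted_only]
    if not use:
        raise ValueError("no accepted edges: the constraint system is empty")
    if n_nodes is None:
        n_nodes = max(max(e.i, e.j) for e in use) + 1
    rows, cols, vals = [], [], []
    b = np.zeros((len(use), 2))
    for r, e in enumerate(use):
        if not (0 <= e.i < n_nodes and 0 <= e.j < n_nodes):
            raise ValueError(
                f"edge ({e.i}, {e.j}) references a node outside 0..{n_nodes - 1}"
            )
        w = np.sqrt(e.inliers) if weight_by_inliers else 1.0
        rows += [r, r]
        cols += [e.i, e.j]
        vals += [w, -w]
        b[r] = np.asarray(e.delta) * w
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(use), n_nodes))
    return PoseGraph(n_nodes, use, A, b)


def solve_positions(graph: PoseGraph, anchor: int = 0) -> PoseGraph:
    """Least-squares positions with the anchor pinned at (0, 0).

    Only the connected component containing the anchor is solvable; other
    nodes get NaN positions and ``placed=False``.  The anchored system is
    solved exactly (dense least squares on the reduced matrix), so
    consistent constraint sets are recovered without error.
    """
    A, b = graph.A, graph.b
    if not (0 <= anchor < graph.n_nodes):
        raise ValueError(f"anchor {anchor} is not a node of the graph")

    adj = (abs(A).T @ abs(A)) > 0
    n_comp, labels = connected_components(adj, directed=False)
    in_comp = labels == labels[anchor]
    # nodes that appear in no edge are their own components
    touched = np.asarray(abs(A).sum(axis=0)).ravel() > 0
    solve_nodes = np.flatnonzero(in_comp & touched)
    solve_nodes = solve_nodes[solve_nodes != anchor]

    row_mask = np.ones(A.shape[0], bool)  # rows fully inside the component
    for r, e in enumerate(graph.edges):
        row_mask[r] = in_comp[e.i] and in_comp[e.j]

    positions = np.full((graph.n_nodes, 2), np.nan)
    positions[anchor] = 0.0
    if len(solve_nodes):
        A_red = A[row_mask][:, solve_nodes].toarray()
        b_red = b[row_mask]
        sol, *_ = np.linalg.lstsq(A_red, b_red, rcond=None)
        positions[solve_nodes] = sol

    graph.positions = positions
    graph.placed = ~np.isnan(positions[:, 0])
    return graph


@dataclass
class DriftReport:
    """Residual diagnostics of a solved pose graph."""

    residuals: np.ndarray  # (n_edges, 2), (x_i - x_j) - delta per axis
    max_residual: float  # max |residual| over edges and axes
    rms_residual: float
    chained_positions: np.ndarray  # (n_nodes, 2) from consecutive edges only


def drift_report(graph: PoseGraph) -> DriftReport:
    """Per-edge residuals of the global solution, plus the positions that
    plain sequential chaining (integrating only consecutive-frame deltas)
    would give — the quantity bundle adjustment exists to improve on."""
    if graph.positions is None:
        raise ValueError("graph has not been solved")
    pos = graph.positions
    res = np.array(
        [pos[e.i] - pos[e.j] - np.asarray(e.delta) for e in graph.edges]
    )
    finite = res[np.isfinite(res).all(axis=1)]
    max_r = float(np.abs(finite).max()) if len(finite) else 0.0
    rms = float(np.sqrt((finite**2).mean())) if len(finite) else 0.0

    chained = np.full((graph.n_nodes, 2), np.nan)
    chained[0] = 0.0
    consecutive = {}
    for e in graph.edges:
        if e.j == e.i + 1:
            consecutive.setdefault(e.i, e)  # first estimate wins
        elif e.i == e.j + 1:
            consecutive.setdefault(
                e.j,
                PairwiseTranslation(e.j, e.i, (-e.delta[0], -e.delta[1]), e.inliers),
            )
    for k in range(graph.n_nodes - 1):
        e = consecutive.get(k)
        if e is None or np.isnan(chained[k]).any():
            continue
        # x_i - x_j = delta with (i=k, j=k+1)  =>  x_{k+1} = x_k - delta
        chained[k + 1] = chained[k] - np.asarray(e.delta)
    return DriftReport(res, max_r, rms, chained)


def write_positions_csv(graph: PoseGraph, path: str | Path) -> None:
    """Write solved positions as ``frame,x,y`` (placed nodes only)."""
    if graph.positions is None:
        raise ValueError("graph has not been solved")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "x", "y"])
        for k, (x, y) in enumerate(graph.positions):
            if graph.placed[k]:
                writer.writerow([k, repr(float(x)), repr(float(y))])


def read_positions_csv(path: str | Path) -> dict[int, tuple[float, float]]:
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["frame"])] = (float(row["x"]), float(row["y"]))
    return out
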