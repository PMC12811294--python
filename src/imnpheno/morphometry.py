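"""Neurite skeleton morphometry and nuclear/cytoplasmic intensity ratios.

Skeletons come from topology-preserving thinning; lengths count diagonal
steps as sqrt(2) x pixel size. The skeleton is condensed into a graph
whose nodes are endpoints and junction clusters and whose edges are
branches; spurs shorter than a configurable pruning length are dropped
before branch counting, because thinning artifacts otherwise dominate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

SQRT2 = math.sqrt(2.0)

# diagonal-first neighbor offsets; a diagonal step is skipped when an
# orthogonal two-step path through skeleton pixels exists, so the pixel
# graph has no spurious triangles
_ORTHO = ((0, 1), (1, 0))
_DIAG = ((1, 1), (1, -1))


@dataclass
class SkeletonMetrics:
    """Per-cell skeleton summary (lengths in µm)."""

    total_length_um: float
    branch_count: int
    endpoint_count: int
    junction_count: int


def _pixel_graph(skel: np.ndarray) -> dict[tuple[int, int], list[tuple[tuple[int, int], float]]]:
    """Adjacency of skeleton pixels; diagonal edges carry weight sqrt(2)
    and are dropped when shortcut by two orthogonal edges."""
    pts = set(zip(*np.nonzero(skel)))
    adj: dict[tuple[int, int], list[tuple[tuple[int, int], float]]] = {p: [] for p in pts}
    for (y, x) in pts:
        for dy, dx in _ORTHO:
            q = (y + dy, x + dx)
            if q in pts:
                adj[(y, x)].append((q, 1.0))
                adj[q].append(((y, x), 1.0))
        for dy, dx in _DIAG:
            q = (y + dy, x + dx)
            if q in pts:
                if ((y, x + dx) in pts) or ((y + dy, x) in pts):
                    continue  # orthogonal shortcut exists
                adj[(y, x)].append((q, SQRT2))
                adj[q].append(((y, x), SQRT2))
    return adj


def _junction_clusters(adj, degrees) -> dict[tuple[int, int], int]:
    """Group 8-adjacent junction pixels (degree >= 3) into one junction id."""
    junc = [p for p, d in degrees.items() if d >= 3]
    cluster: dict[tuple[int, int], int] = {}
    cid = 0
    for p in junc:
        if p in cluster:
            continue
        stack = [p]
        cluster[p] = cid
        while stack:
            u = stack.pop()
            for (y, x) in junc:
                if (y, x) not in cluster and abs(y - u[0]) <= 1 and abs(x - u[1]) <= 1:
                    cluster[(y, x)] = cid
                    stack.append((y, x))
        cid += 1
    return cluster


def _branches(adj):
    """Decompose the pixel graph into branches between node pixels.

    Node pixels are those with degree != 2 (endpoints, junctions,
    isolated); each branch is (start, end, length_px, n_steps). Pure
    cycles with no node pixel yield one closed branch.
    """
    degrees = {p: len(n) for p, n in adj.items()}
    nodes = {p for p, d in degrees.items() if d != 2}
    visited: set[frozenset] = set()
    branches = []
    for start in sorted(nodes):
        for (nbr, w0) in adj[start]:
            e = frozenset((start, nbr))
            if e in visited:
                continue
            visited.add(e)
            length = w0
            prev, cur = start, nbr
            while cur not in nodes:
                nxt = [(q, w) for q, w in adj[cur] if q != prev]
                if not nxt:
                    break
                q, w = nxt[0]
                visited.add(frozenset((cur, q)))
                length += w
                prev, cur = cur, q
            branches.append((start, cur, length))
    # closed loops of pure degree-2 pixels
    loop_pixels = [p for p, d in degrees.items() if d == 2]
    remaining = [p for p in loop_pixels if not any(frozenset((p, q)) in visited for q, _ in adj[p])]
    while remaining:
        start = remaining[0]
        length = 0.0
        prev, cur = None, start
        while True:
            nxt = [(q, w) for q, w in adj[cur] if q != prev]
            if not nxt:
                break
            q, w = nxt[0]
            if frozenset((cur, q)) in visited:
                break
            visited.add(frozenset((cur, q)))
            length += w
            prev, cur = cur, q
            if cur == start:
                break
        branches.append((start, start, length))
        remaining = [p for p in remaining if not any(frozenset((p, q)) in visited for q, _ in adj[p])]
    return branches, degrees, nodes


def skeletonize_cell(
    mask: np.ndarray,
    pixel_size_um: float,
    prune_um: float = 2.0,
    soma_mask: np.ndarray | None = None,
) -> SkeletonMetrics:
    """Thin a cell mask and summarize its skeleton graph.

    Total length sums all skeleton edges (diagonals as sqrt(2) px);
    branch count is the number of graph edges between nodes after
    removing terminal spurs shorter than ``prune_um``. When
    ``soma_mask`` is given, skeleton pixels inside the soma are removed
    first, so the metrics describe the neurites only.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(mask)
    if soma_mask is not None:
        skel = skel & ~np.asarray(soma_mask, dtype=bool)
    if not skel.any():
        return SkeletonMetrics(0.0, 0, 0, 0)
    adj = _pixel_graph(skel)
    branches, degrees, nodes = _branches(adj)
    if not branches:  # single isolated pixel(s)
        return SkeletonMetrics(0.0, 0, int(sum(1 for d in degrees.values() if d == 0)), 0)
    total = sum(b[2] for b in branches) * pixel_size_um
    clusters = _junction_clusters(adj, degrees)

    def _is_tip(p) -> bool:
        return degrees.get(p, 0) <= 1

    kept = [
        b for b in branches
        if not ((_is_tip(b[0]) or _is_tip(b[1])) and b[2] * pixel_size_um < prune_um)
    ]
    end_nodes = {p for b in kept for p in (b[0], b[1]) if _is_tip(p)}
    junction_ids = {clusters[p] for b in kept for p in (b[0], b[1]) if p in clusters}
    return SkeletonMetrics(
        total_length_um=float(total),
        branch_count=len(kept),
        endpoint_count=len(end_nodes),
        junction_count=len(junction_ids),
    )


# --------------------------------------------------------------------------
# TDP-43 nuclear/cytoplasmic partitioning
# --------------------------------------------------------------------------

@dataclass
class LocalizationRatio:
    """Cytoplasm/nucleus mean-intensity ratio of one cell."""

    cell_id: int
    nuclear_mean: float
    cytoplasmic_mean: float
    ratio: float


def measure_tdp43(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    frame,
    cell_id: int = 0,
) -> LocalizationRatio:
    """Cytoplasm/nucleus mean intensity ratio on one segmented cell.

    Means (not integrated intensities) are used in both compartments so
    the ratio does not depend on compartment areas. The cytoplasm is the
    cell region minus the nucleus and must be non-empty; the nucleus
    must lie inside the cell.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    if not np.all(cell[nuc]):
        raise ValueError("nucleus not contained in cell region")
    cyto = cell & ~nuc
    if not cyto.any():
        raise ValueError("empty cytoplasm (cell minus nucleus)")
    if not nuc.any():
        raise ValueError("empty nucleus mask")
    img = frame.data if hasattr(frame, "data") else np.asarray(frame, dtype=float)
    nuclear = float(img[nuc].mean())
    cytoplasmic = float(img[cyto].mean())
    if nuclear <= 0:
        raise ValueError("nuclear mean intensity must be > 0 for a valid ratio")
    return LocalizationRatio(cell_id, nuclear, cytoplasmic, cytoplasmic / nuclear)


def pair_nuclei_to_cells(
    nuclei_labels: np.ndarray, cell_labels: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Assign each nucleus to the cell containing its centroid.

    Nuclei whose centroid falls on background stay unassigned; cells
    receiving more than one nucleus are flagged multinucleate (their
    pairs are reported but excluded from ratio statistics downstream).
    Returns the pairing table and a QC report.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    cell_labels = np.asarray(cell_labels)
    if nuclei_labels.shape != cell_labels.shape:
        raise ValueError("masks must be on the same frame")
    ids = [int(i) for i in np.unique(nuclei_labels) if i > 0]
    rows, unassigned = [], []
    for nid in ids:
        cy, cx = ndi.center_of_mass(nuclei_labels == nid)
        cell = int(cell_labels[int(round(cy)), int(round(cx))])
        if cell == 0:
            unassigned.append(nid)
        else:
            rows.append({"nucleus_id": nid, "cell_id": cell})
    pairs = pd.DataFrame(rows, columns=["nucleus_id", "cell_id"])
    if len(pairs):
        counts = pairs["cell_id"].value_counts()
        multinucleate = sorted(int(c) for c in counts[counts > 1].index)
    else:
        multinucleate = []
    pairs["multinucleate"] = pairs["cell_id"].isin(multinucleate) if len(pairs) else []
    report = {"unassigned_nuclei": unassigned, "multinucleate_cells": multinucleate}
    return pairs, report
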