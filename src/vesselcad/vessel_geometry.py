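"""Vessel centerline geometry.

Skeletonizes binary vessel masks into one-voxel-wide centerlines, organizes
the skeleton as a graph of edges between endpoints/junctions, assigns vessel
voxels to branches, and evaluates two per-centerline-voxel sequences that the
anatomical features are built on:

* the radius profile ``Rn`` — the Euclidean distance-transform value at each
  skeleton voxel (inscribed-sphere radius, in voxels), and
* the tumor-distance profile — the Euclidean distance from each skeleton
  voxel to the nearest tumor voxel.

All operations assume an isotropic grid so voxel units equal millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .mask_io import GridError, StructureSet

#: minimum spur length (voxels) kept during pruning
MIN_SPUR_LENGTH = 5

_NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=int,
)


class EmptyMaskError(ValueError):
    """Operation requires a non-empty mask."""


class ConsistencyError(ValueError):
    """Inputs disagree (path outside mask, length mismatch, ...)."""


@dataclass
class Skeleton:
    """A centerline graph.

    ``edges`` are ordered voxel paths (arrays of shape (L, 3), 26-connected);
    ``nodes`` are the endpoint/junction voxels; ``surface_map`` assigns every
    vessel surface voxel its nearest skeleton voxel (ties broken toward the
    lowest lexicographic index).
    """

    points: np.ndarray
    nodes: list[tuple[int, int, int]]
    edges: list[np.ndarray]
    surface_map: dict[tuple[int, int, int], tuple[int, int, int]]
    shape: tuple[int, int, int]


@dataclass
class VesselBranch:
    vessel_name: str
    path: np.ndarray
    branch_mask: np.ndarray
    radius_seq: Optional[np.ndarray] = None
    tumor_dist_seq: Optional[np.ndarray] = None


def _adjacency(points: np.ndarray) -> dict[tuple, list[tuple]]:
    """26-connectivity adjacency over skeleton voxels."""
    index = {tuple(p): True for p in points}
    adj: dict[tuple, list[tuple]] = {}
    for p in points:
        tp = tuple(p)
        nbrs = []
        for off in _NEIGHBOR_OFFSETS:
            q = (tp[0] + off[0], tp[1] + off[1], tp[2] + off[2])
            if q in index:
                nbrs.append(q)
        adj[tp] = nbrs
    return adj


def _trace_edges(
    adj: dict[tuple, list[tuple]],
) -> tuple[list[tuple], list[list[tuple]]]:
    """Split the skeleton voxel graph into nodes and node-to-node paths."""
    nodes = sorted(p for p, nb in adj.items() if len(nb) != 2)
    node_set = set(nodes)
    # pure cycles (every voxel degree 2): anchor at the lexicographic minimum
    if not nodes and adj:
        visited: set[tuple] = set()
        for p in sorted(adj):
            if p not in visited:
                comp = {p}
                stack = [p]
                while stack:
                    for q in adj[stack.pop()]:
                        if q not in comp:
                            comp.add(q)
                            stack.append(q)
                visited |= comp
                anchor = min(comp)
                nodes.append(anchor)
                node_set.add(anchor)
        nodes = sorted(nodes)

    edges: list[list[tuple]] = []
    seen_steps: set[tuple[tuple, tuple]] = set()
    for n in nodes:
        for first in adj[n]:
            if (n, first) in seen_steps:
                continue
            path = [n, first]
            seen_steps.add((n, first))
            prev, cur = n, first
            while cur not in node_set:
                nxt = [q for q in adj[cur] if q != prev]
                if not nxt:
                    break  # isolated dangling voxel
                prev, cur = cur, nxt[0]
                path.append(cur)
            if cur in node_set:
                seen_steps.add((cur, prev))
            edges.append(path)
    # deduplicate undirected edges (each traced once from either end)
    unique: list[list[tuple]] = []
    keys: set[tuple] = set()
    for path in edges:
        key = (path[0], path[-1], len(path), path[min(1, len(path) - 1)])
        rkey = (path[-1], path[0], len(path), path[max(len(path) - 2, 0)])
        if key in keys or rkey in keys:
            continue
        keys.add(key)
        unique.append(path)
    return nodes, unique


def _orient(path: list[tuple]) -> list[tuple]:
    """Order the path from the lexicographically lower endpoint."""
    return path if path[0] <= path[-1] else path[::-1]


def _prune(points: set[tuple], radius_at: dict[tuple, float]) -> set[tuple]:
    """Iteratively drop terminal spurs shorter than max(5, 0.5 * local radius).

    Spurs are terminal edges attached to a junction; an isolated edge (both
    ends degree 1) is never pruned, so a clean tube keeps its single edge.
    """
    points = set(points)
    while True:
        adj = _adjacency(np.array(sorted(points)))
        nodes, edges = _trace_edges(adj)
        degree = {p: len(nb) for p, nb in adj.items()}
        removed = False
        for path in edges:
            a, b = path[0], path[-1]
            deg_a, deg_b = degree.get(a, 0), degree.get(b, 0)
            if deg_a == 1 and deg_b >= 3:
                tip, junction = a, b
            elif deg_b == 1 and deg_a >= 3:
                tip, junction = b, a
            else:
                continue
            threshold = max(MIN_SPUR_LENGTH, 0.5 * radius_at.get(junction, 0.0))
            if len(path) - 1 < threshold:
                points -= set(path) - {junction}
                removed = True
        if not removed:
            return points


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    face = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=face, border_value=0)
    return np.argwhere(mask & ~interior)


def _nearest_with_lex_ties(tree: cKDTree, pts: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Index of the nearest point; exact ties resolved to the lex-lowest point."""
    k = min(8, len(pts))
    dist, idx = tree.query(query, k=k)
    if k == 1:
        return np.atleast_1d(idx)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    out = np.empty(len(query), dtype=int)
    for i in range(len(query)):
        tied = idx[i][dist[i] <= dist[i, 0] + 1e-9]
        cand = pts[tied]
        order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
        out[i] = tied[order[0]]
    return out


def skeletonize_graph(mask: np.ndarray, prune: bool = True) -> Skeleton:
    """Extract a pruned medial-axis skeleton graph from a binary mask.

    Topological 3D thinning produces a one-voxel-wide centerline; terminal
    spurs shorter than ``max(5, 0.5 * local radius)`` voxels (a by-product of
    surface discretization on digital tubes) are removed. Each vessel surface
    voxel is mapped to its nearest skeleton voxel — the mapping ``f(v)`` used
    by the contact-length feature.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise EmptyMaskError("cannot skeletonize an empty mask")
    skel = skeletonize(mask)
    pts = {tuple(p) for p in np.argwhere(skel)}
    if not pts:  # thinning can erase a 1-2 voxel blob; keep a seed voxel
        pts = {tuple(np.argwhere(mask)[0])}
    edt = ndimage.distance_transform_edt(mask)
    if prune and len(pts) > 1:
        radius_at = {p: float(edt[p]) for p in pts}
        pts = _prune(pts, radius_at)
    points = np.array(sorted(pts), dtype=int)
    adj = _adjacency(points)
    nodes, raw_edges = _trace_edges(adj)
    edges = [np.array(_orient(p), dtype=int) for p in raw_edges]

    surface = _surface_voxels(mask)
    tree = cKDTree(points)
    nearest = _nearest_with_lex_ties(tree, points, surface)
    surface_map = {
        tuple(s): tuple(points[j]) for s, j in zip(surface, nearest)
    }
    return Skeleton(
        points=points, nodes=nodes, edges=edges,
        surface_map=surface_map, shape=mask.shape,
    )


def split_branches(
    s: StructureSet | np.ndarray,
    sk: Skeleton,
    vessel_name: str = "",
    manual_labels: Optional[np.ndarray] = None,
) -> list[VesselBranch]:
    """Partition a vessel mask into branches, one per skeleton edge.

    Every vessel voxel is assigned to the edge containing its nearest skeleton
    voxel, so branch masks are pairwise disjoint and cover the vessel exactly.
    ``manual_labels`` (an integer volume on the same grid) overrides the
    automatic assignment where positive.
    """
    if isinstance(s, StructureSet):
        mask = s.vessels[vessel_name]
        tumor = s.tumor
    else:
        mask = np.asarray(s).astype(bool)
        tumor = None
    if mask.shape != sk.shape:
        raise GridError("skeleton was built on a different grid")
    if manual_labels is not None and manual_labels.shape != mask.shape:
        raise GridError("manual branch-label volume grid mismatch")

    vox = np.argwhere(mask)
    if manual_labels is not None:
        ids = manual_labels[mask]
        branches = []
        for lab in sorted(set(int(v) for v in ids if v > 0)):
            bmask = mask & (manual_labels == lab)
            path = [p for e in sk.edges for p in e if bmask[tuple(p)]]
            if not path:
                path = [p for p in sk.points if bmask[tuple(p)]]
            branches.append(
                VesselBranch(vessel_name, np.array(path, dtype=int), bmask)
            )
    elif not sk.edges:
        branches = [VesselBranch(vessel_name, sk.points.copy(), mask.copy())]
    else:
        edge_pts = np.concatenate(sk.edges)
        edge_ids = np.concatenate(
            [np.full(len(e), i) for i, e in enumerate(sk.edges)]
        )
        tree = cKDTree(edge_pts)
        _, nearest = tree.query(vox, k=1)
        assigned = edge_ids[nearest]
        branches = []
        for i, edge in enumerate(sk.edges):
            bmask = np.zeros_like(mask)
            sel = vox[assigned == i]
            bmask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
            branches.append(VesselBranch(vessel_name, edge.copy(), bmask))

    for b in branches:
        if len(b.path):
            b.radius_seq = radius_profile(b, mask)
            if tumor is not None and tumor.any():
                b.tumor_dist_seq = tumor_distance_profile(b, tumor)
    return branches


def radius_profile(b: VesselBranch, mask: np.ndarray) -> np.ndarray:
    """Per-voxel inscribed radius along the branch path (voxels).

    The radius at a skeleton voxel is the Euclidean distance-transform value
    of the vessel mask there.
    """
    mask = np.asarray(mask).astype(bool)
    idx = tuple(b.path.T)
    if not mask[idx].all():
        raise ConsistencyError("branch path leaves the vessel mask")
    edt = ndimage.distance_transform_edt(mask)
    return edt[idx].astype(float)


def tumor_distance_profile(b: VesselBranch, tumor: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean distance from the branch path to the tumor."""
    tumor = np.asarray(tumor).astype(bool)
    if tumor.sum() == 0:
        raise EmptyMaskError("tumor mask is empty")
    dist = ndimage.distance_transform_edt(~tumor)
    return dist[tuple(b.path.T)].astype(float)
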