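"""Collagen fibre network extraction from the SHG channel.

A FIRE-style (FIbeR Extraction) tracer: nucleation points are seeded at
local maxima of the distance transform of the thresholded SHG mask, and
each seed propagates node chains along the local ridge direction (the
structure-tensor principal axis) in fixed-length steps.  Two departures
from the classic algorithm: edges are subject to an explicit edge-length
threshold, and a propagating tip may connect to ANY existing node within
that threshold, not only to nodes sharing its parent — so crossing or
touching fibres fuse into one connected network.

Extraction is fully deterministic: every candidate ordering is
lexicographic in (row, col) and there is no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from fibrekit.tensor_texture import structure_tensor_field, orientation_angles


@dataclass
class FireParams:
    """Tunables of the network tracer.

    intensity_threshold: mask threshold on the (denoised, [0,1]-scaled) SHG
        raster; None selects Otsu's threshold at run time.
    nucleation_spacing: minimum spacing in px between nucleation points.
    step: propagation step length in px.
    edge_threshold: maximum allowed edge length in px; also the capture
        radius within which a tip fuses to an existing node.
    angle_tol: maximum direction change in degrees both for tip propagation
        and for fibre tracing through a junction.
    """

    intensity_threshold: float | None = None
    nucleation_spacing: float = 10.0
    step: float = 3.0
    edge_threshold: float = 5.0
    angle_tol: float = 70.0


@dataclass
class FibreNetwork:
    """Spatial graph tracing fibre centrelines.

    nodes: (N, 2) float array of (row, col) pixel positions.
    edges: list of (u, v) node-index pairs, u < v, no duplicates or
        self-edges; every edge is no longer than the edge threshold it was
        created under.
    """

    nodes: np.ndarray
    edges: list[tuple[int, int]] = dc_field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_length(self, u: int, v: int) -> float:
        return float(np.linalg.norm(self.nodes[u] - self.nodes[v]))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, pos in enumerate(self.nodes):
            g.add_node(i, pos=tuple(pos))
        for u, v in self.edges:
            g.add_edge(u, v, length=self.edge_length(u, v))
        return g


@dataclass
class Fibre:
    """An ordered node path through the network.

    length is the summed Euclidean edge length, displacement the end-to-end
    distance; waviness = displacement / length lies in (0, 1] and equals 1
    for a perfectly straight fibre.  angle is the end-to-end orientation in
    degrees folded into [0, 180).
    """

    path: list[int]
    length: float
    displacement: float
    waviness: float
    angle: float

    @classmethod
    def from_path(cls, path: list[int], nodes: np.ndarray) -> "Fibre":
        if len(path) < 2:
            raise ValueError("a fibre needs at least 2 nodes")
        if len(set(path)) != len(path):
            raise ValueError("fibre path revisits a node")
        pts = nodes[np.asarray(path)]
        seg = np.diff(pts, axis=0)
        length = float(np.linalg.norm(seg, axis=1).sum())
        disp_vec = pts[-1] - pts[0]
        displacement = float(np.linalg.norm(disp_vec))
        angle = math.degrees(math.atan2(disp_vec[0], disp_vec[1])) % 180.0
        return cls(
            path=list(path),
            length=length,
            displacement=displacement,
            waviness=displacement / length if length > 0 else 1.0,
            angle=angle,
        )


def _nucleation_points(mask: np.ndarray, spacing: float) -> np.ndarray:
    """Local maxima of the distance transform of the fibre mask, greedily
    thinned to a minimum spacing in lexicographic-then-depth order."""
    dist = ndimage.distance_transform_edt(mask)
    if dist.max() == 0:
        return np.empty((0, 2), dtype=float)
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (dist == ndimage.maximum_filter(dist, footprint=footprint, mode="constant")) & (
        dist > 0
    )
    rows, cols = np.nonzero(local_max)
    depth = dist[rows, cols]
    # deepest ridge points first; ties broken lexicographically for determinism
    order = np.lexsort((cols, rows, -depth))
    cand = np.column_stack([rows, cols]).astype(float)[order]
    picked = np.empty((len(cand), 2), dtype=float)
    n_picked = 0
    sp2 = spacing * spacing
    for pt in cand:
        if n_picked == 0 or (
            ((picked[:n_picked] - pt) ** 2).sum(axis=1).min() >= sp2
        ):
            picked[n_picked] = pt
            n_picked += 1
    return picked[:n_picked]


class _NetworkBuilder:
    """Mutable growing network with vectorized nearest-node queries."""

    _CHUNK = 256

    def __init__(self) -> None:
        self._buf = np.empty((self._CHUNK, 2), dtype=float)
        self._n = 0
        self.edges: set[tuple[int, int]] = set()

    def add_node(self, pos: np.ndarray) -> int:
        if self._n == len(self._buf):
            self._buf = np.vstack([self._buf, np.empty_like(self._buf)])
        self._buf[self._n] = pos
        self._n += 1
        return self._n - 1

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            return
        self.edges.add((min(u, v), max(u, v)))

    def nearest(self, pos: np.ndarray, radius: float, exclude: set[int]) -> int | None:
        if self._n == 0:
            return None
        d = np.linalg.norm(self._buf[: self._n] - pos, axis=1)
        for i in exclude:
            d[i] = np.inf
        best = int(np.argmin(d))  # argmin takes the lowest index on ties
        return best if d[best] < radius else None

    def finish(self) -> FibreNetwork:
        return FibreNetwork(nodes=self._buf[: self._n].copy(), edges=sorted(self.edges))


def _ridge_direction(angle_deg: float) -> np.ndarray:
    """Unit (row, col) vector along a folded orientation angle."""
    rad = math.radians(angle_deg)
    return np.array([math.sin(rad), math.cos(rad)])


def extract_network(shg: np.ndarray, params: FireParams | None = None) -> FibreNetwork:
    """Trace the fibre network of a (denoised) SHG raster.

    Seeds nucleation points on ridge maxima of the thresholded mask, then
    propagates each seed in both directions along the local orientation
    field, laying down nodes every ``params.step`` px while the path stays
    on the mask and bends by less than ``params.angle_tol`` per step.  A tip
    that comes within ``params.edge_threshold`` of any existing node fuses
    to it and stops.  An all-below-threshold raster yields an empty network.
    """
    params = params or FireParams()
    arr = np.asarray(shg, dtype=float)
    thr = params.intensity_threshold
    if thr is None:
        thr = float(threshold_otsu(arr)) if arr.max() > arr.min() else float("inf")
    mask = arr > thr
    if not mask.any():
        return FibreNetwork(nodes=np.empty((0, 2), dtype=float), edges=[])

    tensor = structure_tensor_field(arr, derivative_sigma=1.0, window_sigma=2.0)
    angle_map = orientation_angles(tensor)
    seeds = _nucleation_points(mask, params.nucleation_spacing)

    builder = _NetworkBuilder()
    nrows, ncols = arr.shape
    cos_tol = math.cos(math.radians(params.angle_tol))
    max_steps = int(2 * (nrows + ncols) / params.step) + 4

    def on_mask(pos: np.ndarray) -> bool:
        r, c = int(round(pos[0])), int(round(pos[1]))
        return 0 <= r < nrows and 0 <= c < ncols and bool(mask[r, c])

    def local_dir(pos: np.ndarray) -> np.ndarray:
        r = min(max(int(round(pos[0])), 0), nrows - 1)
        c = min(max(int(round(pos[1])), 0), ncols - 1)
        return _ridge_direction(float(angle_map[r, c]))

    for seed in seeds:
        if not on_mask(seed):
            continue
        near = builder.nearest(seed, params.edge_threshold, exclude=set())
        if near is not None:
            continue  # an existing chain already covers this ridge
        seed_id = builder.add_node(seed)
        axis = local_dir(seed)
        for sense in (+1.0, -1.0):
            prev_id = seed_id
            direction = sense * axis
            pos = seed.copy()
            for _ in range(max_steps):
                ridge = local_dir(pos)
                # orient the axial ridge direction along the current heading
                if float(np.dot(ridge, direction)) < 0:
                    ridge = -ridge
                if float(np.dot(ridge, direction)) < cos_tol:
                    break  # ridge bends away faster than the tolerance
                nxt = pos + params.step * ridge
                if not on_mask(nxt):
                    break
                captured = builder.nearest(nxt, params.edge_threshold, exclude={prev_id})
                if captured is not None:
                    builder.add_edge(prev_id, captured)
                    break
                node_id = builder.add_node(nxt)
                builder.add_edge(prev_id, node_id)
                direction = ridge
                prev_id = node_id
                pos = nxt
    return builder.finish()


def identify_fibres(
    net: FibreNetwork, angle_tol: float = 70.0
) -> tuple[list[Fibre], list[list[int]]]:
    """Split the network into individual fibres.

    Every degree-1 node nucleates one fibre.  Tracing walks from the tip,
    at each junction taking the unused edge that minimizes the direction
    change, and stops when the best continuation would bend by more than
    ``angle_tol`` degrees or revisit a node.  Each edge belongs to at most
    one fibre, so a simple path graph yields a single fibre rather than one
    per tip.  Cycle components with no degree-1 node nucleate no fibre and
    are returned in the residual list.
    """
    g = net.to_graph()
    used: set[tuple[int, int]] = set()

    def edge_key(u: int, v: int) -> tuple[int, int]:
        return (min(u, v), max(u, v))

    tips = sorted(n for n in g.nodes if g.degree(n) == 1)
    fibres: list[Fibre] = []
    cos_tol = math.cos(math.radians(angle_tol))

    for tip in tips:
        free = [v for v in g.neighbors(tip) if edge_key(tip, v) not in used]
        if not free:
            continue  # this tip's fibre was already traced from the other end
        path = [tip]
        current = tip
        heading: np.ndarray | None = None
        while True:
            candidates = []
            for v in sorted(g.neighbors(current)):
                if edge_key(current, v) in used or v in path:
                    continue
                step = net.nodes[v] - net.nodes[current]
                norm = np.linalg.norm(step)
                if norm == 0:
                    continue
                u_step = step / norm
                cosang = 1.0 if heading is None else float(np.dot(heading, u_step))
                candidates.append((cosang, v, u_step))
            if not candidates:
                break
            cosang, v, u_step = max(candidates, key=lambda t: (t[0], -t[1]))
            if heading is not None and cosang < cos_tol:
                break
            used.add(edge_key(current, v))
            path.append(v)
            heading = u_step
            current = v
        if len(path) >= 2:
            fibres.append(Fibre.from_path(path, net.nodes))

    residual_cycles = [
        sorted(comp)
        for comp in nx.connected_components(g)
        if len(comp) >= 3 and all(g.degree(n) != 1 for n in comp)
    ]
    return fibres, residual_cycles


_SENTINEL = float("nan")


def fibre_metrics(fibres: list[Fibre]) -> dict[str, float]:
    """Global averages over identified fibres.

    Returns n_fibres, mean_waviness, mean_length (px), mean_angle (degrees,
    axial circular mean folded into [0, 180)).  An empty list yields NaN
    sentinels for the means.
    """
    if not fibres:
        return {
            "n_fibres": 0.0,
            "mean_waviness": _SENTINEL,
            "mean_length": _SENTINEL,
            "mean_angle": _SENTINEL,
        }
    angles = np.radians(2.0 * np.array([f.angle for f in fibres]))
    mean_angle = (math.degrees(math.atan2(np.sin(angles).mean(), np.cos(angles).mean())) / 2.0) % 180.0
    return {
        "n_fibres": float(len(fibres)),
        "mean_waviness": float(np.mean([f.waviness for f in fibres])),
        "mean_length": float(np.mean([f.length for f in fibres])),
        "mean_angle": float(mean_angle),
    }


def network_metrics(
    net: FibreNetwork, fibres: list[Fibre], connectivity_mode: str = "algebraic"
) -> dict[str, float]:
    """Spectral and connectivity summaries of the fibre network.

    degree = 2|E|/|V| over the whole network; the adjacency max-eigenvalue
    and the connectivity are computed per connected component of >= 3 nodes
    and averaged; crosslink_density = (number of nodes with degree >= 3) /
    (number of fibres).  An empty network yields NaN sentinels.

    connectivity_mode "algebraic" (default) uses the second-smallest
    Laplacian eigenvalue; "node" uses the mean pairwise node connectivity
    (slower, O(V^2) max-flow calls per component).
    """
    if connectivity_mode not in ("algebraic", "node"):
        raise ValueError("connectivity_mode must be 'algebraic' or 'node'")
    out = {
        "degree": _SENTINEL,
        "max_eigenvalue": _SENTINEL,
        "connectivity": _SENTINEL,
        "crosslink_density": _SENTINEL,
    }
    if net.n_nodes == 0:
        return out
    g = net.to_graph()
    out["degree"] = 2.0 * g.number_of_edges() / g.number_of_nodes()
    eigs, conns = [], []
    for comp in nx.connected_components(g):
        if len(comp) < 3:
            continue
        sub = g.subgraph(comp)
        adj = nx.to_numpy_array(sub, weight=None)
        eigs.append(float(np.linalg.eigvalsh(adj)[-1]))
        if connectivity_mode == "algebraic":
            lap = np.diag(adj.sum(axis=1)) - adj
            conns.append(float(np.sort(np.linalg.eigvalsh(lap))[1]))
        else:
            conns.append(float(nx.average_node_connectivity(sub)))
    if eigs:
        out["max_eigenvalue"] = float(np.mean(eigs))
        out["connectivity"] = float(np.mean(conns))
    crosslinks = sum(1 for n in g.nodes if g.degree(n) >= 3)
    if fibres:
        out["crosslink_density"] = crosslinks / len(fibres)
    return out


def write_network(net: FibreNetwork, path) -> None:
    """Export the network as a plain edge-list text file.

    Lines: ``node <id> <row> <col>`` then ``edge <u> <v>``.
    """
    lines = [f"node {i} {p[0]:.3f} {p[1]:.3f}" for i, p in enumerate(net.nodes)]
    lines += [f"edge {u} {v}" for u, v in net.edges]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_network(path) -> FibreNetwork:
    nodes, edges = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "node":
                nodes.append((float(parts[2]), float(parts[3])))
            elif parts[0] == "edge":
                edges.append((int(parts[1]), int(parts[2])))
    arr = np.asarray(nodes, dtype=float).reshape(-1, 2)
    return FibreNetwork(nodes=arr, edges=[(min(u, v), max(u, v)) for u, v in edges])
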