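"""Vessel/myocyte density, distance, boundary, and vascular-topology analysis.

Works on two-channel 3D volumes (myocyte marker and endothelial marker).
The central quantities are:

* fractional volume -- mask voxels / total voxels, per tile and globally;
* the anisotropy-aware Euclidean distance from every myocyte voxel to its
  nearest vessel voxel;
* the per-row (node-axis) mean distance profile and its four-parameter
  logistic fit, whose inflection row is the objective superior/inferior
  boundary;
* a skeleton-based vessel graph with per-segment length, branch order
  (1 deg = primary artery path) and mean diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from . import fitstats
from .datatypes import LabeledVolume

__all__ = [
    "BinaryMask",
    "DensityMap",
    "DistanceMap",
    "DistanceProfile",
    "SigmoidFit",
    "VesselGraph",
    "threshold_mask",
    "fractional_volume_map",
    "distance_transform",
    "distance_profile",
    "fit_region_boundary",
    "region_split",
    "distance_ecdf",
    "skeletonize_vessels",
    "branch_orders",
    "vessel_diameters",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class BinaryMask:
    mask: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel: str = ""
    method: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class DensityMap:
    """Per-tile fractional volume over the (row, col) plane, full z depth."""

    values: np.ndarray           # (n_tile_rows, n_tile_cols), in [0, 1]
    counts: np.ndarray           # foreground voxels per tile
    totals: np.ndarray           # voxels per tile (edge tiles may be smaller)
    tile_shape: tuple[int, int]  # (rows, cols) voxels per tile
    global_fraction: float


@dataclass
class DistanceMap:
    """Myocyte-voxel distances to the nearest vessel voxel, um (NaN elsewhere)."""

    distances_um: np.ndarray
    voxel_size_um: tuple[float, float, float]

    @property
    def values(self) -> np.ndarray:
        d = self.distances_um
        return d[np.isfinite(d)]


@dataclass
class DistanceProfile:
    """Per-row mean +/- SEM of myocyte-to-vessel distance along the node axis."""

    rows: np.ndarray       # row-bin centers, voxel-row units
    mean_um: np.ndarray    # NaN where a row holds no myocyte voxels
    sem_um: np.ndarray
    n: np.ndarray
    row_bin: int = 1

    @property
    def missing(self) -> np.ndarray:
        return self.n == 0


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit of a distance profile.

    ``boundary_row`` is the inflection x0 -- the objective split between
    the superior (low-distance) and inferior (high-distance) regions.
    """

    d_sup_um: float
    d_inf_um: float
    boundary_row: float
    steepness: float
    rss: float
    converged: bool
    degenerate: bool
    n_rows: int

    @property
    def fold_change(self) -> float:
        return self.d_inf_um / self.d_sup_um if self.d_sup_um else float("nan")


@dataclass
class VesselGraph:
    """Skeleton graph of a vessel mask.

    Nodes are junction/endpoint skeleton voxels (keyed by voxel coords);
    segments are the degree-2 chains between them, each with its voxel
    path, polyline length in um, and optionally a branch order and mean
    diameter.
    """

    graph: nx.MultiGraph
    segments: list[dict] = field(default_factory=list)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_branches: int = 0

    @property
    def total_length_um(self) -> float:
        return float(sum(s["length_um"] for s in self.segments))

    @property
    def n_segments(self) -> int:
        return len(self.segments)


# --------------------------------------------------------------------------
# masks and densities
# --------------------------------------------------------------------------

def threshold_mask(channel: np.ndarray,
                   voxel_size_um: tuple[float, float, float],
                   method: str = "otsu", *, threshold: float | None = None,
                   percentile: float | None = None,
                   name: str = "") -> BinaryMask:
    """Threshold an intensity channel into a binary mask.

    ``method`` is one of ``fixed`` (requires ``threshold``), ``otsu``
    (automatic, errors on a flat channel) or ``percentile`` (requires
    ``percentile``).  The method and value used are recorded on the mask.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(channel) == 0:
            raise ValueError("Otsu thresholding is undefined on a flat channel")
        thr = float(threshold_otsu(channel))
    elif method == "percentile":
        if percentile is None:
            raise ValueError("percentile thresholding requires a percentile")
        thr = float(np.percentile(channel, percentile))
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return BinaryMask(mask=channel > thr, voxel_size_um=voxel_size_um,
                      channel=name, method=method, threshold=thr)


def fractional_volume_map(mask: BinaryMask,
                          tile_shape: tuple[int, int] = (32, 32)) -> DensityMap:
    """Tile the (row, col) plane and compute per-tile fractional volume.

    Each tile spans the full z depth; edge tiles are truncated and counted
    exactly, so tile counts sum to the global foreground count.
    """
    m = mask.mask
    tr, tc = tile_shape
    if tr <= 0 or tc <= 0:
        raise ValueError("tile dimensions must be positive")
    _, nrow, ncol = m.shape
    n_tr = -(-nrow // tr)
    n_tc = -(-ncol // tc)
    counts = np.zeros((n_tr, n_tc), dtype=np.int64)
    totals = np.zeros((n_tr, n_tc), dtype=np.int64)
    for i in range(n_tr):
        for j in range(n_tc):
            tile = m[:, i * tr:(i + 1) * tr, j * tc:(j + 1) * tc]
            counts[i, j] = tile.sum()
            totals[i, j] = tile.size
    values = counts / totals
    return DensityMap(values=values, counts=counts, totals=totals,
                      tile_shape=(tr, tc),
                      global_fraction=float(m.mean()))


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def distance_transform(myocyte_mask: np.ndarray, vessel_mask: np.ndarray,
                       voxel_size_um: tuple[float, float, float]) -> DistanceMap:
    """Exact anisotropic Euclidean distance from myocyte to nearest vessel.

    Computed with the Euclidean distance transform of the vessel-mask
    complement, sampled at the per-axis voxel size, then restricted to
    myocyte voxels (all other voxels are NaN).  Overlapping voxels have
    distance zero.
    """
    myo = np.asarray(myocyte_mask, dtype=bool)
    ves = np.asarray(vessel_mask, dtype=bool)
    if myo.shape != ves.shape:
        raise ValueError("mask shapes differ")
    if not ves.any():
        raise ValueError("vessel mask is empty: distances are undefined")
    edt = ndimage.distance_transform_edt(~ves, sampling=voxel_size_um)
    out = np.full(myo.shape, np.nan)
    out[myo] = edt[myo]
    return DistanceMap(distances_um=out, voxel_size_um=tuple(voxel_size_um))


def distance_profile(dmap: DistanceMap, row_bin: int = 1) -> DistanceProfile:
    """Mean +/- SEM myocyte-to-vessel distance per node-axis row bin.

    Rows (bins of ``row_bin`` voxel rows) containing no myocyte voxel are
    reported as NaN with n = 0 rather than zero.
    """
    d = dmap.distances_um
    if not np.isfinite(d).any():
        raise ValueError("distance map holds no myocyte voxels")
    nrow = d.shape[1]
    n_bins = -(-nrow // row_bin)
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        vals = d[:, b * row_bin:(b + 1) * row_bin, :]
        vals = vals[np.isfinite(vals)]
        n[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            sem[b] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    rows = (np.arange(n_bins) + 0.5) * row_bin
    return DistanceProfile(rows=rows, mean_um=mean, sem_um=sem, n=n,
                           row_bin=row_bin)


def fit_region_boundary(profile: DistanceProfile) -> SigmoidFit:
    """Fit the distance profile with a 4-parameter logistic.

    The inflection row x0 is reported as the superior/inferior boundary.
    A flat profile yields a degenerate fit with an undefined boundary.
    """
    keep = ~profile.missing
    if keep.sum() < 8:
        raise ValueError("need at least 8 non-missing rows for a boundary fit")
    res = fitstats.fit_logistic4(profile.rows[keep], profile.mean_um[keep])
    return SigmoidFit(
        d_sup_um=res["lower"], d_inf_um=res["upper"],
        boundary_row=res["x0"], steepness=res["k"], rss=res.rss,
        converged=res.converged, degenerate=res.degenerate,
        n_rows=int(keep.sum()))


def region_split(volume: np.ndarray, boundary_row: float,
                 axis: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Split an array at the boundary along the node axis.

    Rows strictly below the boundary are superior; the boundary row itself
    belongs to the inferior part.  The split is exhaustive and disjoint.
    """
    nrow = volume.shape[axis]
    cut = int(np.ceil(boundary_row))
    cut = max(0, min(cut, nrow))
    sup = np.take(volume, np.arange(0, cut), axis=axis)
    inf = np.take(volume, np.arange(cut, nrow), axis=axis)
    return sup, inf


def distance_ecdf(dmap: DistanceMap,
                  boundary_row: float) -> dict[str, dict]:
    """Per-region empirical CDF and mean of myocyte-to-vessel distances."""
    sup, inf = region_split(dmap.distances_um, boundary_row, axis=1)
    out: dict[str, dict] = {}
    for name, part in (("superior", sup), ("inferior", inf)):
        vals = np.sort(part[np.isfinite(part)])
        if vals.size == 0:
            out[name] = {"empty": True, "x_um": np.array([]),
                         "cdf": np.array([]), "mean_um": float("nan"),
                         "n": 0}
            continue
        cdf = np.arange(1, vals.size + 1) / vals.size
        out[name] = {"empty": False, "x_um": vals, "cdf": cdf,
                     "mean_um": float(vals.mean()), "n": int(vals.size)}
    return out


# --------------------------------------------------------------------------
# vessel skeleton graph
# --------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [(dz, dr, dc) for dz in (-1, 0, 1) for dr in (-1, 0, 1)
     for dc in (-1, 0, 1) if (dz, dr, dc) != (0, 0, 0)])


def _step_length(a: np.ndarray, b: np.ndarray,
                 voxel: np.ndarray) -> float:
    return float(np.linalg.norm((a - b) * voxel))


def skeletonize_vessels(vessel_mask: np.ndarray,
                        voxel_size_um: tuple[float, float, float],
                        min_spur_voxels: int = 3) -> VesselGraph:
    """Skeletonize a vessel mask and trace its segment graph.

    The 3D medial-axis skeleton is decomposed into segments between
    junction (>=3 skeleton neighbors, 26-connectivity) and endpoint
    voxels.  Segment length is the anisotropic polyline length of the
    voxel path.  Terminal segments shorter than ``min_spur_voxels`` are
    pruned as skeletonization spurs.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        return VesselGraph(graph=nx.MultiGraph(), segments=[],
                           voxel_size_um=tuple(voxel_size_um))
    skel = skeletonize(mask)
    voxel = np.asarray(voxel_size_um, dtype=float)

    coords = np.argwhere(skel)
    coord_set = {tuple(c) for c in coords}
    degree: dict[tuple[int, int, int], int] = {}
    for c in coord_set:
        deg = sum(
            (c[0] + o[0], c[1] + o[1], c[2] + o[2]) in coord_set
            for o in _NEIGHBOR_OFFSETS)
        degree[c] = deg

    nodes = {c for c, d in degree.items() if d != 2}
    graph = nx.MultiGraph()
    segments: list[dict] = []
    visited_edges: set[frozenset] = set()

    def neighbors(c):
        for o in _NEIGHBOR_OFFSETS:
            nb = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
            if nb in coord_set:
                yield nb

    def walk(start, first):
        """Follow the chain from node `start` through `first` to the next node."""
        path = [start, first]
        prev, cur = start, first
        while cur not in nodes:
            nxt = [nb for nb in neighbors(cur) if nb != prev]
            if not nxt:
                break  # open chain end (degree-1 handled via nodes normally)
            prev, cur = cur, nxt[0]
            path.append(cur)
        return path

    for node in nodes:
        for nb in neighbors(node):
            edge_key = frozenset((node, nb))
            if edge_key in visited_edges:
                continue
            path = walk(node, nb)
            # mark traversed unit edges so the chain is not walked twice
            for a, b in zip(path[:-1], path[1:]):
                visited_edges.add(frozenset((a, b)))
            end = path[-1]
            length = sum(
                _step_length(np.array(a), np.array(b), voxel)
                for a, b in zip(path[:-1], path[1:]))
            segments.append({"path": path, "ends": (path[0], end),
                             "length_um": length, "n_voxels": len(path)})

    # isolated cycles (no junction/endpoint voxel): trace each as one segment
    chain_voxels = coord_set - nodes
    in_segment = {v for s in segments for v in s["path"]}
    remaining = chain_voxels - in_segment
    while remaining:
        start = next(iter(remaining))
        path = [start]
        prev, cur = None, start
        while True:
            nxt = [nb for nb in neighbors(cur) if nb != prev]
            if not nxt or nxt[0] == start:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        remaining -= set(path)
        length = sum(_step_length(np.array(a), np.array(b), voxel)
                     for a, b in zip(path[:-1], path[1:]))
        segments.append({"path": path, "ends": (path[0], path[-1]),
                         "length_um": length, "n_voxels": len(path)})

    # prune terminal spurs: short segments with a free (endpoint) end
    def is_terminal(seg):
        a, b = seg["ends"]
        return degree.get(a, 0) == 1 or degree.get(b, 0) == 1

    kept = [s for s in segments
            if not (is_terminal(s) and s["n_voxels"] < min_spur_voxels
                    and len(segments) > 1)]
    if not kept and segments:
        kept = [max(segments, key=lambda s: s["n_voxels"])]

    for i, seg in enumerate(kept):
        seg["id"] = i
        a, b = seg["ends"]
        graph.add_node(a, kind="endpoint" if degree.get(a, 0) <= 1 else "junction")
        graph.add_node(b, kind="endpoint" if degree.get(b, 0) <= 1 else "junction")
        graph.add_edge(a, b, key=i, segment=i, length_um=seg["length_um"])

    return VesselGraph(graph=graph, segments=kept,
                       voxel_size_um=tuple(voxel_size_um))


def branch_orders(vgraph: VesselGraph,
                  root_um: tuple[float, float, float]) -> VesselGraph:
    """Assign branch orders: the primary artery path is 1 deg, each
    branching off it increments the order.

    The root is the graph node nearest ``root_um`` (physical coords).
    Starting there, the 1 deg (primary artery) path is traced greedily:
    at every junction the continuation is the unassigned segment with the
    largest mean diameter -- the widest-vessel rule used in vascular tree
    analysis (run :func:`vessel_diameters` first; segment length is the
    fallback criterion).  Side branches off an order-o path start order
    o+1 paths, traced the same way.  A maximal path of constant order is
    one branch; branch ids are recorded per segment, so the number of
    distinct branches is ``len({s['branch_id'] ...})``.  Segments outside
    the root's connected component keep order -1.
    """
    g = vgraph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty vessel graph")
    voxel = np.asarray(vgraph.voxel_size_um)
    root_pt = np.asarray(root_um, dtype=float)
    root = min(g.nodes,
               key=lambda c: np.linalg.norm((np.asarray(c) + 0.5) * voxel
                                            - root_pt))

    seg_by_id = {s["id"]: s for s in vgraph.segments}
    for seg in vgraph.segments:
        seg["order"] = -1
        seg["branch_id"] = -1

    def calibre(sid: int) -> float:
        seg = seg_by_id[sid]
        return seg.get("diameter_um") or seg["length_um"]

    assigned: set[int] = set()
    branch_counter = 0
    stack: list[tuple[tuple, int]] = [(root, 1)]
    while stack:
        node, order = stack.pop(0)
        # trace one branch: greedy widest continuation until a dead end
        branch_segs: list[int] = []
        cur = node
        while True:
            options = [
                (data["segment"], nb)
                for _, nb, key, data in g.edges(cur, keys=True, data=True)
                if data["segment"] not in assigned]
            if not options:
                break
            sid, nxt = max(options, key=lambda o: calibre(o[0]))
            seg = seg_by_id[sid]
            seg["order"] = order
            seg["branch_id"] = branch_counter
            assigned.add(sid)
            branch_segs.append(sid)
            # side branches at this node become order+1 starts
            if len(options) > 1:
                stack.append((cur, order + 1))
            cur = nxt
        if branch_segs:
            branch_counter += 1
        # a node can still hold unassigned edges (queued duplicates)
        if any(data["segment"] not in assigned
               for _, _, data in g.edges(node, data=True)):
            stack.append((node, order))
    vgraph.n_branches = branch_counter
    return vgraph


def vessel_diameters(vgraph: VesselGraph,
                     vessel_mask: np.ndarray) -> VesselGraph:
    """Per-segment mean diameter: 2x the distance from each skeleton voxel
    of the segment path to the mask background, averaged along the path."""
    mask = np.asarray(vessel_mask, dtype=bool)
    edt = ndimage.distance_transform_edt(mask, sampling=vgraph.voxel_size_um)
    for seg in vgraph.segments:
        radii = np.array([edt[v] for v in seg["path"]])
        seg["diameter_um"] = float(2.0 * radii.mean()) if radii.size else 0.0
    return vgraph


def analyze_volume(vol: LabeledVolume, *, tile_shape=(32, 32),
                   threshold_method: str = "fixed",
                   threshold: float = 0.5) -> dict:
    """Convenience end-to-end volumetric analysis used by the pipeline."""
    myo = threshold_mask(vol.myocyte_channel, vol.voxel_size_um,
                         threshold_method, threshold=threshold, name="myocyte")
    ves = threshold_mask(vol.vessel_channel, vol.voxel_size_um,
                         threshold_method, threshold=threshold, name="vessel")
    myo_density = fractional_volume_map(myo, tile_shape)
    ves_density = fractional_volume_map(ves, tile_shape)
    dmap = distance_transform(myo.mask, ves.mask, vol.voxel_size_um)
    profile = distance_profile(dmap)
    boundary = fit_region_boundary(profile)
    ecdf = (distance_ecdf(dmap, boundary.boundary_row)
            if not boundary.degenerate else None)
    return {
        "myocyte_mask": myo, "vessel_mask": ves,
        "myocyte_density": myo_density, "vessel_density": ves_density,
        "distance_map": dmap, "profile": profile, "boundary": boundary,
        "ecdf": ecdf,
    }
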