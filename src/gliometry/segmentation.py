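"""Nucleus detection, sparse-arbor segmentation, skeletonization, territory.

Morphometry operates on 2-D maximum-intensity projections; sparse labelling
guarantees that the connected component around a nucleus is a single cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, skeletonize

from .io import Config, ImageStack

__all__ = [
    "NucleusSet",
    "ArborMask",
    "Skeleton",
    "Territory",
    "detect_nuclei",
    "segment_arbor",
    "skeletonize_arbor",
    "compute_territory",
]


@dataclass
class NucleusSet:
    """Detected nuclei: centroids (µm, (y, x)), radii, and a label grid."""

    centroids_um: np.ndarray  # (n, 2)
    radii_um: np.ndarray
    labels: np.ndarray  # (y, x) int grid, 0 = background, 1..n per nucleus
    pixel_size_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.centroids_um = np.asarray(self.centroids_um, dtype=float).reshape(-1, 2)
        self.radii_um = np.asarray(self.radii_um, dtype=float).reshape(-1)
        present = set(np.unique(self.labels).tolist()) - {0}
        if present and present != set(range(1, len(self.centroids_um) + 1)):
            raise ValueError("nucleus labels must be dense 1..n")

    def __len__(self) -> int:
        return len(self.centroids_um)


@dataclass
class ArborMask:
    """Binary footprint of one astrocyte on the max projection."""

    cell_id: int
    mask: np.ndarray  # (y, x) bool
    nucleus_yx_um: tuple[float, float]
    pixel_size_um: tuple[float, float]
    border_touching: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if cc_label(self.mask).max() > 1:
            raise ValueError("arbor mask must be a single connected component")


@dataclass
class Skeleton:
    """Thinned arbor with its branch graph (nodes/edges in pixel coords)."""

    cell_id: int
    pixels: np.ndarray  # (n, 2) (y, x) skeleton pixel coordinates
    endpoints: np.ndarray  # (m, 2)
    graph: nx.Graph  # nodes = pixel tuples; edges carry length_um + path
    pixel_size_um: tuple[float, float]

    @property
    def pixels_um(self) -> np.ndarray:
        return self.pixels * np.asarray(self.pixel_size_um)

    @property
    def endpoints_um(self) -> np.ndarray:
        return self.endpoints * np.asarray(self.pixel_size_um)

    def total_length_um(self) -> float:
        return float(sum(d["length_um"] for _, _, d in self.graph.edges(data=True)))


@dataclass
class Territory:
    """Convex spatial domain of one astrocyte (hull of its arbor mask)."""

    cell_id: int
    polygon_um: np.ndarray  # (k, 2) hull vertices (y, x), µm
    area_um2: float
    volume_um3: float


# ---------------------------------------------------------------------------

def detect_nuclei(stack: ImageStack, channel: str, cfg: Config | None = None) -> NucleusSet:
    """Multiscale LoG blob detection of nuclei on the max projection.

    Centroids are refined by intensity-weighted centre of mass in a local
    window; per-nucleus masks come from Otsu thresholding within twice the
    detected radius.
    """
    cfg = cfg or Config()
    img = stack.max_projection(channel)
    py, px = stack.voxel_size_um[1], stack.voxel_size_um[2]
    if abs(py - px) > 1e-9:
        raise ValueError("detect_nuclei assumes isotropic in-plane pixels")
    r_px = cfg.nucleus_radius_um / px
    sigma = r_px / np.sqrt(2.0)
    blobs = blob_log(
        img.astype(float),
        min_sigma=0.5 * sigma,
        max_sigma=1.5 * sigma,
        num_sigma=5,
        threshold=cfg.nucleus_min_response,
    )
    ny, nx_ = img.shape
    centroids = []
    radii = []
    for by, bx, bs in blobs:
        w = int(round(1.5 * r_px))
        y0, y1 = max(0, int(by) - w), min(ny, int(by) + w + 1)
        x0, x1 = max(0, int(bx) - w), min(nx_, int(bx) + w + 1)
        win = img[y0:y1, x0:x1]
        if win.sum() > 0:
            cy, cx = ndi.center_of_mass(win)
            centroids.append((y0 + cy, x0 + cx))
        else:
            centroids.append((by, bx))
        radii.append(bs * np.sqrt(2.0))
    centroids_px = np.asarray(centroids, dtype=float).reshape(-1, 2)
    order = np.lexsort((centroids_px[:, 1], centroids_px[:, 0])) if len(centroids_px) else []
    centroids_px = centroids_px[order]
    radii = np.asarray(radii)[order] if len(radii) else np.empty(0)

    labels = np.zeros(img.shape, dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centroids_px, radii), start=1):
        w = int(np.ceil(2 * r))
        y0, y1 = max(0, int(cy) - w), min(ny, int(cy) + w + 1)
        x0, x1 = max(0, int(cx) - w), min(nx_, int(cx) + w + 1)
        win = img[y0:y1, x0:x1]
        if win.max() > win.min():
            m = win > threshold_otsu(win)
        else:
            m = win > 0
        yy, xx = np.mgrid[y0:y1, x0:x1]
        m &= (yy - cy) ** 2 + (xx - cx) ** 2 <= (2 * r) ** 2
        region = labels[y0:y1, x0:x1]
        region[m & (region == 0)] = i
    return NucleusSet(
        centroids_um=centroids_px * np.array([py, px]),
        radii_um=radii * px,
        labels=labels,
        pixel_size_um=(py, px),
    )


def segment_arbor(
    stack: ImageStack,
    channel: str,
    nucleus_yx_um: tuple[float, float],
    cfg: Config | None = None,
    cell_id: int = 0,
) -> ArborMask:
    """Segment the sparse-labelled arbor around one nucleus.

    Thresholds the reporter max projection (Otsu in a window around the
    nucleus, or the fixed ``arbor_threshold`` when set), keeps the connected
    component containing the nucleus centroid, and fills holes.
    """
    cfg = cfg or Config()
    img = stack.max_projection(channel).astype(float)
    py, px = stack.voxel_size_um[1], stack.voxel_size_um[2]
    iy = int(round(nucleus_yx_um[0] / py))
    ix = int(round(nucleus_yx_um[1] / px))
    ny, nx_ = img.shape
    if not (0 <= iy < ny and 0 <= ix < nx_):
        raise ValueError("nucleus centroid outside the image")

    if cfg.arbor_threshold > 0:
        thr = cfg.arbor_threshold
    else:
        w = int(round(cfg.arbor_window_um / 2 / px))
        win = img[max(0, iy - w) : iy + w + 1, max(0, ix - w) : ix + w + 1]
        if win.max() <= win.min():
            raise ValueError("no arbor found: window has no contrast at the nucleus")
        thr = threshold_otsu(win)
    binary = img > thr
    if not binary[iy, ix]:
        raise ValueError("no arbor found: nucleus centroid below threshold")
    comps = cc_label(binary, connectivity=2)
    mask = comps == comps[iy, ix]
    mask = ndi.binary_fill_holes(mask)
    border = bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())
    return ArborMask(
        cell_id=cell_id,
        mask=mask,
        nucleus_yx_um=tuple(map(float, nucleus_yx_um)),
        pixel_size_um=(py, px),
        border_touching=border,
    )


# ---------------------------------------------------------------------------
# skeleton

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_graph(coords: np.ndarray, pixel_size: tuple[float, float]) -> nx.Graph:
    py, px = pixel_size
    pset = {tuple(c) for c in coords}
    g = nx.Graph()
    g.add_nodes_from(pset)
    for y, x in pset:
        for dy, dx in _OFFSETS:
            nb = (y + dy, x + dx)
            if nb in pset and not g.has_edge((y, x), nb):
                g.add_edge((y, x), nb, length_um=float(np.hypot(dy * py, dx * px)))
    return g


def _condense(g: nx.Graph) -> nx.Graph:
    """Collapse degree-2 chains into branch edges carrying polyline paths."""
    nodes = [n for n in g.nodes if g.degree(n) != 2]
    if not nodes:  # pure cycle
        nodes = [min(g.nodes)] if g.number_of_nodes() else []
    bg = nx.MultiGraph()
    bg.add_nodes_from(nodes)
    seen = set()
    for n in nodes:
        for nb in g.neighbors(n):
            if (n, nb) in seen:
                continue
            path = [n, nb]
            length = g.edges[n, nb]["length_um"]
            prev, cur = n, nb
            while g.degree(cur) == 2 and cur not in nodes:
                nxt = next(x for x in g.neighbors(cur) if x != prev)
                length += g.edges[cur, nxt]["length_um"]
                path.append(nxt)
                prev, cur = cur, nxt
            seen.add((prev, cur))
            seen.add((nb, n))
            bg.add_edge(n, cur, length_um=length, path=path)
    simple = nx.Graph()
    simple.add_nodes_from(bg.nodes)
    for u, v, d in bg.edges(data=True):
        if simple.has_edge(u, v):
            if d["length_um"] >= simple.edges[u, v]["length_um"]:
                continue
        simple.add_edge(u, v, **d)
    return simple


def skeletonize_arbor(mask: ArborMask, cfg: Config | None = None) -> Skeleton:
    """Topological thinning plus spur pruning and branch-graph construction.

    Spurs (endpoint branches) shorter than ``min_spur_um`` are removed
    iteratively; edge lengths are polyline µm lengths.
    """
    cfg = cfg or Config()
    if not mask.mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skeletonize(mask.mask)
    coords = np.argwhere(skel)
    g = _pixel_graph(coords, mask.pixel_size_um)

    # prune short spurs on the pixel graph
    changed = True
    while changed:
        changed = False
        bg = _condense(g)
        for u, v, d in list(bg.edges(data=True)):
            u_end = g.degree(u) == 1
            v_end = g.degree(v) == 1
            if (u_end != v_end) and d["length_um"] < cfg.min_spur_um:
                path = d["path"]
                drop = path[:-1] if u_end else path[1:]
                interior = [p for p in drop if p in g]
                g.remove_nodes_from(interior)
                changed = True
        if g.number_of_nodes() == 0:
            break
    if g.number_of_nodes() == 0:
        # whole skeleton shorter than the spur threshold; keep the raw pixels
        g = _pixel_graph(coords, mask.pixel_size_um)

    final_coords = np.array(sorted(g.nodes))
    endpoints = np.array(sorted(n for n in g.nodes if g.degree(n) == 1)).reshape(-1, 2)
    return Skeleton(
        cell_id=mask.cell_id,
        pixels=final_coords,
        endpoints=endpoints,
        graph=_contract_junctions(_condense(g), g),
        pixel_size_um=mask.pixel_size_um,
    )


def _contract_junctions(branch_graph: nx.Graph, pixel_graph: nx.Graph) -> nx.Graph:
    """Merge adjacent junction pixels into single branch nodes.

    Thinning leaves small clusters of mutually adjacent degree>=3 pixels at
    crossings; each cluster is one topological branch point.
    """
    junctions = [n for n in pixel_graph.nodes if pixel_graph.degree(n) >= 3]
    rep: dict[tuple, tuple] = {}
    if junctions:
        sub = pixel_graph.subgraph(junctions)
        for comp in nx.connected_components(sub):
            r = min(comp)
            for n in comp:
                rep[n] = r
    out = nx.Graph()
    for n in branch_graph.nodes:
        out.add_node(rep.get(n, n))
    for u, v, d in branch_graph.edges(data=True):
        ru, rv = rep.get(u, u), rep.get(v, v)
        if ru == rv:
            continue  # intra-cluster sliver
        if out.has_edge(ru, rv) and out.edges[ru, rv]["length_um"] >= d["length_um"]:
            continue
        out.add_edge(ru, rv, **d)
    return out


def compute_territory(mask: ArborMask, depth_um: float = 5.0) -> Territory:
    """Convex hull of the arbor mask, scaled to µm.

    Volume is hull area times the stack depth (thin-stack convention).
    """
    from scipy.spatial import ConvexHull

    pts = np.argwhere(mask.mask).astype(float) * np.asarray(mask.pixel_size_um)
    if len(pts) < 3:
        raise ValueError("mask too small for a territory hull")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # collinear / degenerate
        raise ValueError(f"degenerate mask, no 2-D hull: {exc}") from exc
    verts = pts[hull.vertices]
    area = float(hull.volume)  # 2-D ConvexHull: .volume is the area
    return Territory(
        cell_id=mask.cell_id,
        polygon_um=verts,
        area_um2=area,
        volume_um3=area * depth_um,
    )
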