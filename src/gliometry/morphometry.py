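"""Per-astrocyte shape statistics.

The measured quantities mirror the standard regional-astrocyte phenotyping
readouts: distance from the nucleus to the tip of the longest branch,
length-to-width ratio of the arbor footprint (maximum Feret diameter over
the perpendicular extent), orientation of the elongation axis relative to
the septal midline folded to [0, 90] degrees with pie-chart binning,
territory area/volume, and a Sholl intersection profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Config, RegionAtlas
from .segmentation import ArborMask, Skeleton, Territory
from .synth import axis_angle_deg

__all__ = [
    "MorphometryRecord",
    "longest_branch",
    "feret_axis",
    "length_width_ratio",
    "orientation_angle",
    "bin_angles",
    "sholl_profile",
    "measure_cell",
]


@dataclass
class MorphometryRecord:
    cell_id: int
    longest_branch_um: float
    lw_ratio: float
    orientation_deg: float  # NaN when the cell is too round to orient
    angle_bin: str
    territory_area_um2: float
    territory_volume_um3: float
    region_label: int = 0
    longest_branch_fallback: bool = False


def _hull_vertices_um(mask: ArborMask) -> np.ndarray:
    from scipy.spatial import ConvexHull

    pts = np.argwhere(mask.mask).astype(float) * np.asarray(mask.pixel_size_um)
    if len(pts) < 3:
        raise ValueError("mask has fewer than 3 pixels")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:
        raise ValueError(f"degenerate (collinear) mask: {exc}") from exc
    return pts[hull.vertices]


def feret_axis(mask: ArborMask) -> tuple[float, float, np.ndarray]:
    """Maximum Feret diameter, perpendicular extent, and the Feret axis.

    The maximum caliper distance is attained between two convex-hull
    vertices, so the exact answer is the maximum pairwise distance over
    hull vertices; width is the hull extent along the perpendicular axis.
    """
    verts = _hull_vertices_um(mask)
    diff = verts[:, None, :] - verts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = float(np.sqrt(d2[i, j]))
    axis = (verts[j] - verts[i]) / length
    perp = np.array([-axis[1], axis[0]])
    proj = verts @ perp
    width = float(proj.max() - proj.min())
    return length, width, axis


def longest_branch(skel: Skeleton, nucleus_yx_um: tuple[float, float]) -> tuple[float, bool]:
    """Maximum Euclidean distance (µm) from the nucleus to a skeleton endpoint.

    A cyclic skeleton has no endpoints; then the maximum over all skeleton
    pixels is used and flagged (second return value True).
    """
    nucleus = np.asarray(nucleus_yx_um, dtype=float)
    if len(skel.pixels) == 0:
        raise ValueError("empty skeleton")
    if len(skel.endpoints) > 0:
        pts = skel.endpoints_um
        fallback = False
    else:
        pts = skel.pixels_um
        fallback = True
    return float(np.max(np.linalg.norm(pts - nucleus, axis=1))), fallback


def length_width_ratio(mask: ArborMask) -> float:
    """Maximum Feret diameter over the perpendicular extent (>= 1)."""
    length, width, _ = feret_axis(mask)
    if width <= 0:
        raise ValueError("degenerate mask: zero width")
    return length / width


def orientation_angle(mask: ArborMask, atlas: RegionAtlas, cfg: Config | None = None) -> float:
    """Acute angle (degrees) between the elongation axis and the midline.

    Near-isotropic cells (length/width below ``orientation_min_elongation``)
    have no meaningful axis; NaN is returned and downstream binning skips
    them ("undefined" orientation).
    """
    cfg = cfg or Config()
    length, width, axis = feret_axis(mask)
    if width <= 0 or length / width < cfg.orientation_min_elongation:
        return float("nan")
    return axis_angle_deg(axis, atlas.midline_axis)


def bin_angles(
    angles_deg: np.ndarray | list[float], edges_deg: list[float] | None = None
) -> np.ndarray:
    """Fractions of defined-orientation cells per angle bin.

    Bins are half-open [a, b) with the last bin closed at 90; fractions are
    over cells with a defined orientation and sum to 1.
    """
    edges = np.asarray(edges_deg if edges_deg is not None else [0.0, 30.0, 60.0, 90.0], float)
    if np.any(np.diff(edges) <= 0) or edges[0] != 0 or edges[-1] != 90:
        raise ValueError("edges must be strictly increasing and span [0, 90]")
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) == 0:
        raise ValueError("no defined-orientation angles to bin")
    counts, _ = np.histogram(a, bins=edges)  # histogram closes the last bin
    return counts / counts.sum()


def angle_bin_label(angle_deg: float, edges_deg: list[float]) -> str:
    if not np.isfinite(angle_deg):
        return "undefined"
    edges = np.asarray(edges_deg, float)
    idx = min(np.searchsorted(edges, angle_deg, side="right") - 1, len(edges) - 2)
    return f"[{edges[idx]:g},{edges[idx + 1]:g})"


def sholl_profile(
    skel: Skeleton, nucleus_yx_um: tuple[float, float], step_um: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Skeleton crossings of concentric circles around the nucleus.

    Returns ``(radii_um, intersection_counts)`` for radii step, 2*step, ...
    up to the longest-branch distance.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    nucleus = np.asarray(nucleus_yx_um, dtype=float)
    rmax, _ = longest_branch(skel, nucleus_yx_um)
    radii = np.arange(step_um, rmax + 1e-9, step_um)
    counts = np.zeros(len(radii), dtype=int)
    scale = np.asarray(skel.pixel_size_um)
    for _, _, d in skel.graph.edges(data=True):
        path = np.asarray(d["path"], dtype=float) * scale
        dist = np.linalg.norm(path - nucleus, axis=1)
        for k, r in enumerate(radii):
            s = np.sign(dist - r)
            s[s == 0] = 1e-12  # touching counts as one crossing
            counts[k] += int(np.sum(s[:-1] * s[1:] < 0))
    return radii, counts


def measure_cell(
    mask: ArborMask,
    skel: Skeleton,
    territory: Territory,
    atlas: RegionAtlas,
    cfg: Config | None = None,
) -> MorphometryRecord:
    """Assemble the full morphometry record for one segmented astrocyte."""
    cfg = cfg or Config()
    lb, fallback = longest_branch(skel, mask.nucleus_yx_um)
    lw = length_width_ratio(mask)
    angle = orientation_angle(mask, atlas, cfg)
    return MorphometryRecord(
        cell_id=mask.cell_id,
        longest_branch_um=lb,
        lw_ratio=lw,
        orientation_deg=angle,
        angle_bin=angle_bin_label(angle, cfg.angle_bin_edges_deg),
        territory_area_um2=territory.area_um2,
        territory_volume_um3=territory.volume_um3,
        region_label=atlas.region_of_point(mask.nucleus_yx_um),
        longest_branch_fallback=fallback,
    )
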