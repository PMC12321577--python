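"""Marker-colocalization cell census and regional lineage fractions.

Classifies each detected cell as positive/negative for nuclear marker
channels by a background-referenced intensity threshold, then aggregates
lineage fractions (e.g. what proportion of Sox9+ astrocytes carry a
lineage reporter) and astrocyte densities per septal region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import Config, ImageStack, RegionAtlas
from .segmentation import NucleusSet

__all__ = [
    "LineageFractions",
    "classify_cells",
    "lineage_fractions",
    "regional_cell_density",
]


@dataclass
class LineageFractions:
    region_label: int
    region: str
    n_ref: int
    n_lineage: int
    n_double: int
    fraction_of_ref: float  # NaN when n_ref == 0 (undefined, not 0)
    fraction_of_lineage: float
    density_per_mm2: float


def classify_cells(
    stack: ImageStack,
    nuclei: NucleusSet,
    markers: list[str],
    atlas: RegionAtlas | None = None,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Per-nucleus marker intensities and positivity calls.

    For each nucleus the mean max-projected intensity inside its mask is
    computed per marker; a cell is positive when that mean exceeds
    background mean + k * background s.d. (default k = 3), with background
    estimated from pixels outside all dilated nuclear masks. Deterministic
    given intensities and thresholds.
    """
    cfg = cfg or Config()
    labels = nuclei.labels
    bg_mask = ndi.binary_dilation(labels > 0, iterations=3)
    if np.all(bg_mask):
        raise ValueError("no background pixels available outside nuclear masks")
    idx = np.arange(1, len(nuclei) + 1)
    rows: dict[str, object] = {
        "cell_id": idx - 1,
        "y_um": nuclei.centroids_um[:, 0],
        "x_um": nuclei.centroids_um[:, 1],
    }
    if atlas is not None:
        regions = [atlas.region_of_point(c) for c in nuclei.centroids_um]
        rows["region_label"] = regions
        rows["region"] = [
            atlas.label_map.get(r, "outside atlas") if r != 0 else "outside atlas"
            for r in regions
        ]
    for marker in markers:
        img = stack.max_projection(marker).astype(float)
        bg = img[~bg_mask]
        thr = float(bg.mean() + cfg.marker_threshold_k * bg.std())
        means = ndi.labeled_comprehension(img, labels, idx, np.mean, float, np.nan)
        rows[f"{marker}_mean"] = means
        rows[f"{marker}_positive"] = means > thr
    return pd.DataFrame(rows)


def lineage_fractions(
    census: pd.DataFrame,
    atlas: RegionAtlas,
    ref_marker: str,
    lineage_marker: str,
) -> list[LineageFractions]:
    """Regional lineage proportions from a cell census table.

    ``fraction_of_ref`` is the proportion of reference-marker+ cells that
    are double-positive (e.g. lineage-derived astrocytes within the total
    astrocyte population); ``fraction_of_lineage`` divides by the lineage
    marginal instead. A region with no reference cells is reported as
    undefined (NaN), not zero.
    """
    ref_col, lin_col = f"{ref_marker}_positive", f"{lineage_marker}_positive"
    for col in (ref_col, lin_col, "region_label"):
        if col not in census.columns:
            raise ValueError(f"census table lacks column {col!r}")
    out = []
    for lab in (1, 2, 3, 4):
        name = atlas.label_map[lab]
        sub = census[census["region_label"] == lab]
        n_ref = int(sub[ref_col].sum())
        n_lin = int(sub[lin_col].sum())
        n_double = int((sub[ref_col] & sub[lin_col]).sum())
        area_mm2 = atlas.region_area_um2(lab) * 1e-6
        out.append(
            LineageFractions(
                region_label=lab,
                region=name,
                n_ref=n_ref,
                n_lineage=n_lin,
                n_double=n_double,
                fraction_of_ref=n_double / n_ref if n_ref else float("nan"),
                fraction_of_lineage=n_double / n_lin if n_lin else float("nan"),
                density_per_mm2=n_ref / area_mm2 if area_mm2 > 0 else 0.0,
            )
        )
    return out


def regional_cell_density(
    census: pd.DataFrame, atlas: RegionAtlas, ref_marker: str
) -> dict[str, float]:
    """Reference-marker+ cells per mm^2 for each septal region."""
    ref_col = f"{ref_marker}_positive"
    out = {}
    for lab in (1, 2, 3, 4):
        area_um2 = atlas.region_area_um2(lab)
        if area_um2 <= 0:
            raise ValueError(f"region {atlas.label_map[lab]} has zero area")
        sub = census[census["region_label"] == lab]
        out[atlas.label_map[lab]] = float(sub[ref_col].sum()) / (area_um2 * 1e-6)
    return out
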