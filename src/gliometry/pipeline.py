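"""End-to-end helpers tying the modules into runnable workflows.

These are the routines the command-line interface wraps: simulate a scene,
segment and measure every cell, and the single-cell render/measure loop
used for parameter-recovery studies.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry as morpho
from . import segmentation as seg
from .io import Config, ImageStack, RegionAtlas, write_atlas, write_stack
from .synth import (
    GroundTruthCell,
    SynthConfig,
    make_atlas,
    render_cells,
    sample_arbor,
    substream,
)

__all__ = [
    "simulate_scene",
    "render_single_cell",
    "measure_scene",
    "measure_rendered_cells",
]


def simulate_scene(
    cfg: SynthConfig,
    n_cells: int = 4,
    atlas_shape: tuple[int, int] = (1280, 1280),
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate a multi-cell septum scene with ground truth.

    Cells are placed on a jittered grid spaced widely enough that their
    somata never violate the rendering overlap precondition. Returns the
    atlas, ground-truth cells, and the rendered stack; writes them (plus
    JSON truth) under *out_dir* when given.
    """
    vy, vx = cfg.voxel_size_um[1], cfg.voxel_size_um[2]
    atlas = make_atlas(atlas_shape, pixel_size_um=(vy, vx))
    ny_um = atlas_shape[0] * vy
    nx_um = atlas_shape[1] * vx
    margin = cfg.branch_length_mean_um + 3 * cfg.branch_length_sd_um
    grid = int(np.ceil(np.sqrt(n_cells)))
    ys = np.linspace(margin, ny_um - margin, grid) if grid > 1 else [ny_um / 2]
    xs = np.linspace(margin, nx_um - margin, grid) if grid > 1 else [nx_um / 2]
    cells: list[GroundTruthCell] = []
    cid = 0
    for y in ys:
        for x in xs:
            if cid >= n_cells:
                break
            rng = substream(cfg.seed, "cell", cid)
            jit = rng.uniform(-2.0, 2.0, size=2)
            cell = sample_arbor(
                cfg, (float(y + jit[0]), float(x + jit[1])), rng, cell_id=cid,
                midline_axis=atlas.midline_axis,
            )
            cell.region_label = atlas.region_of_point(cell.soma_yx_um)
            cells.append(cell)
            cid += 1
    stack = render_cells(cells, cfg, atlas, rng=substream(cfg.seed, "render"))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stack(stack, out / "stack.ome.tif")
        write_atlas(atlas, out / "atlas.tif")
        import json

        truth = [
            {
                "cell_id": c.cell_id,
                "soma_yx_um": list(c.soma_yx_um),
                "tips_um": np.asarray(c.true_branch_tips_um).tolist(),
                "true_longest_branch_um": c.true_longest_branch_um,
                "true_orientation_deg": c.true_orientation_deg,
                "region_label": c.region_label,
            }
            for c in cells
        ]
        (out / "truth_cells.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {"atlas": atlas, "cells": cells, "stack": stack}


def render_single_cell(
    cfg: SynthConfig, cell_id: int = 0, field_um: float = 120.0
) -> tuple[ImageStack, RegionAtlas, GroundTruthCell]:
    """Render one astrocyte centred in its own small field.

    This is the acquisition geometry the morphometric assays emulate: one
    sparsely labelled cell per high-magnification stack.
    """
    vy, vx = cfg.voxel_size_um[1], cfg.voxel_size_um[2]
    shape = (int(round(field_um / vy)), int(round(field_um / vx)))
    atlas = make_atlas(shape, pixel_size_um=(vy, vx))
    rng = substream(cfg.seed, "cell", cell_id)
    cell = sample_arbor(
        cfg, (field_um / 2, field_um / 2), rng, cell_id=cell_id,
        midline_axis=atlas.midline_axis,
    )
    cell.region_label = atlas.region_of_point(cell.soma_yx_um)
    stack = render_cells([cell], cfg, atlas, rng=substream(cfg.seed, "render", cell_id))
    return stack, atlas, cell


def measure_scene(
    stack: ImageStack,
    atlas: RegionAtlas,
    cfg: Config | None = None,
    reporter_channel: str = "tdT",
    dapi_channel: str = "DAPI",
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Segment and measure every detectable astrocyte in a scene.

    Border-touching cells are excluded by default (their territories are
    truncated by the field of view).
    """
    cfg = cfg or Config()
    nuclei = seg.detect_nuclei(stack, dapi_channel, cfg)
    records = []
    for i, centroid in enumerate(nuclei.centroids_um):
        try:
            mask = seg.segment_arbor(stack, reporter_channel, tuple(centroid), cfg, cell_id=i)
        except ValueError:
            continue
        if exclude_border and mask.border_touching:
            continue
        skel = seg.skeletonize_arbor(mask, cfg)
        territory = seg.compute_territory(mask, cfg.stack_depth_um)
        records.append(morpho.measure_cell(mask, skel, territory, atlas, cfg))
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def measure_rendered_cells(
    synth_cfg: SynthConfig,
    n_cells: int,
    cfg: Config | None = None,
    field_um: float = 120.0,
) -> pd.DataFrame:
    """Render *n_cells* single-cell fields and measure each one.

    The per-cell substreams make every cell independent of the others;
    returns measured records joined with ground truth columns.
    """
    cfg = cfg or Config()
    rows = []
    for cid in range(n_cells):
        stack, atlas, cell = render_single_cell(synth_cfg, cell_id=cid, field_um=field_um)
        mask = seg.segment_arbor(stack, "tdT", cell.soma_yx_um, cfg, cell_id=cid)
        skel = seg.skeletonize_arbor(mask, cfg)
        territory = seg.compute_territory(mask, cfg.stack_depth_um)
        rec = morpho.measure_cell(mask, skel, territory, atlas, cfg)
        row = dataclasses.asdict(rec)
        row["true_longest_branch_um"] = cell.true_longest_branch_um
        row["true_orientation_deg"] = cell.true_orientation_deg
        rows.append(row)
    return pd.DataFrame(rows)
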