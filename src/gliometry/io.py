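"""Image, atlas, table and configuration I/O.

Conventions used throughout the package:

* voxel grids are indexed ``(channel, z, y, x)``, 0-based;
* physical positions are in micrometres, computed as ``index * voxel_size``
  with voxel centres at integer indices;
* the region atlas is a 2-D coronal-plane label image; 3-D quantities use a
  configurable stack depth (default 5 µm).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "RegionAtlas",
    "Config",
    "REGION_LABELS",
    "read_stack",
    "write_stack",
    "read_atlas",
    "write_atlas",
    "write_table",
    "read_config",
]

#: Fixed septal region labelling: medial septum and the dorsal/intermediate/
#: ventral subdivisions of the lateral septum.
REGION_LABELS: dict[int, str] = {
    0: "background",
    1: "MS",
    2: "dLS",
    3: "iLS",
    4: "vLS",
}


class MetadataError(ValueError):
    """Required image metadata is missing."""


@dataclass
class ImageStack:
    """Multichannel fluorescence z-stack with physical voxel size.

    Parameters
    ----------
    voxels
        Intensity grid indexed ``(channel, z, y, x)``.
    voxel_size_um
        ``(z, y, x)`` micrometres per voxel.
    channel_names
        Ordered unique channel labels, e.g. ``["DAPI", "tdT", "pre", "post"]``.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4-D (channel, z, y, x), got {self.voxels.ndim}-D"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_um}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.voxels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"duplicate channel names: {self.channel_names}")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` grid of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.voxels[idx]

    def max_projection(self, name: str) -> np.ndarray:
        """Maximum-intensity projection of a channel along z."""
        return self.channel(name).max(axis=0)


@dataclass
class RegionAtlas:
    """2-D septal-subregion label image plus the midline axis.

    ``labels`` is a ``(y, x)`` integer grid using :data:`REGION_LABELS`;
    ``midline_axis`` is a ``(y, x)`` unit vector giving the dorsoventral
    midline direction against which orientation angles are measured.
    """

    labels: np.ndarray
    midline_axis: tuple[float, float]
    pixel_size_um: tuple[float, float]
    label_map: dict[int, str] = field(default_factory=lambda: dict(REGION_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer grid")
        present = set(np.unique(self.labels).tolist())
        unknown = sorted(present - set(self.label_map))
        if unknown:
            raise ValueError(f"labels outside the atlas label map: {unknown}")
        axis = np.asarray(self.midline_axis, dtype=float)
        norm = float(np.linalg.norm(axis))
        if norm == 0:
            raise ValueError("midline_axis must be nonzero")
        axis = axis / norm
        self.midline_axis = (float(axis[0]), float(axis[1]))
        self.pixel_size_um = tuple(float(v) for v in self.pixel_size_um)
        if len(self.pixel_size_um) != 2 or any(v <= 0 for v in self.pixel_size_um):
            raise ValueError("pixel_size_um must be two positive values (y, x)")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um[0] * self.pixel_size_um[1]

    def region_mask(self, label: int | str) -> np.ndarray:
        lab = self.label_for(label)
        return self.labels == lab

    def label_for(self, label: int | str) -> int:
        if isinstance(label, str):
            rev = {v: k for k, v in self.label_map.items()}
            if label not in rev:
                raise KeyError(f"unknown region name {label!r}")
            return rev[label]
        if label not in self.label_map:
            raise KeyError(f"unknown region label {label}")
        return int(label)

    def region_area_um2(self, label: int | str) -> float:
        return float(self.region_mask(label).sum()) * self.pixel_area_um2

    def region_of_point(self, yx_um: Sequence[float]) -> int:
        """Region label at a physical (y, x) position; 0 outside the grid."""
        iy = int(round(yx_um[0] / self.pixel_size_um[0]))
        ix = int(round(yx_um[1] / self.pixel_size_um[1]))
        ny, nx = self.labels.shape
        if not (0 <= iy < ny and 0 <= ix < nx):
            return 0
        return int(self.labels[iy, ix])


# ---------------------------------------------------------------------------
# configuration

_CONFIG_RANGES: dict[str, tuple[float, float]] = {
    "stack_depth_um": (0.0, np.inf),
    "nucleus_radius_um": (0.0, np.inf),
    "nucleus_min_response": (0.0, np.inf),
    "cell_isolation_radius_um": (0.0, np.inf),
    "arbor_window_um": (0.0, np.inf),
    "arbor_threshold": (0.0, np.inf),
    "min_spur_um": (0.0, np.inf),
    "orientation_min_elongation": (1.0, np.inf),
    "spot_sigma_um": (0.0, np.inf),
    "psf_sigma_um": (0.0, np.inf),
    "spot_min_response": (0.0, np.inf),
    "min_spot_separation_um": (0.0, np.inf),
    "coloc_max_dist_um": (0.0, np.inf),
    "marker_threshold_k": (0.0, np.inf),
    "sholl_step_um": (0.0, np.inf),
    "seed": (0, 2**31 - 1),
}


@dataclass
class Config:
    """Pipeline tunables, all in micrometres unless noted.

    Unknown keys in a config file are a hard error to prevent silent typos.
    """

    #: 3-D quantities use this z extent (µm); the acquisitions emulated here
    #: are thin confocal stacks.
    stack_depth_um: float = 5.0
    #: Expected nuclear radius (µm) for detection and rendering.
    nucleus_radius_um: float = 3.0
    #: Minimum Laplacian-of-Gaussian response for a nucleus detection.
    nucleus_min_response: float = 0.02
    #: Sparse labelling guarantee: one labelled cell within this radius.
    cell_isolation_radius_um: float = 60.0
    #: Side (µm) of the window around a nucleus used for Otsu thresholding.
    arbor_window_um: float = 80.0
    #: Fixed arbor threshold; overrides Otsu when > 0 (Otsu is degenerate on
    #: two-valued noise-free images).
    arbor_threshold: float = 0.0
    #: Skeleton spurs shorter than this are pruned (one nucleus radius).
    min_spur_um: float = 2.0
    #: Cells less elongated than this have undefined orientation.
    orientation_min_elongation: float = 1.1
    #: Physical punctum Gaussian scale (µm); sub-resolution synaptic spots.
    spot_sigma_um: float = 0.15
    #: Optical PSF sigma (µm); the observed spot scale is
    #: sqrt(spot_sigma^2 + psf_sigma^2).
    psf_sigma_um: float = 0.5
    #: Minimum LoG response for a punctum detection.
    spot_min_response: float = 0.02
    #: Detections closer than this merge, keeping the stronger.
    min_spot_separation_um: float = 0.3
    #: Pre/post pairing distance for colocalized synaptic puncta.
    coloc_max_dist_um: float = 0.5
    #: Marker positivity threshold: background mean + k * background s.d.
    marker_threshold_k: float = 3.0
    #: Radial step of the Sholl profile.
    sholl_step_um: float = 5.0
    #: Angle-bin edges (degrees) for orientation pie fractions.
    angle_bin_edges_deg: list[float] = field(default_factory=lambda: [0.0, 30.0, 60.0, 90.0])
    #: Default random seed for simulation runs.
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _CONFIG_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")
        edges = list(self.angle_bin_edges_deg)
        if edges != sorted(edges) or len(set(edges)) != len(edges):
            raise ValueError("angle_bin_edges_deg must be strictly increasing")
        if edges[0] != 0.0 or edges[-1] != 90.0:
            raise ValueError("angle_bin_edges_deg must span [0, 90]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "Config":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_config(path: str | Path | None) -> Config:
    """Load a TOML config, or the defaults when *path* is None."""
    if path is None:
        return Config()
    return Config.from_toml(path)


# ---------------------------------------------------------------------------
# image I/O

def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a multichannel z-stack from TIFF / OME-TIFF.

    The channel axis comes first in the returned stack. Voxel size is taken
    from OME metadata when present, else from *voxel_size_override*; if
    neither is available a :class:`MetadataError` is raised naming the
    missing fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "CZYX", "ZCYX", "ZYX", "YX"
        meta = _ome_pixel_sizes(tif)
        names = _ome_channel_names(tif)

    data = _to_czyx(data, axes)
    if meta is not None:
        voxel_size = meta
    elif voxel_size_override is not None:
        voxel_size = tuple(float(v) for v in voxel_size_override)
    else:
        raise MetadataError(
            "no PhysicalSizeZ/PhysicalSizeY/PhysicalSizeX metadata in "
            f"{path.name} and no voxel_size_override given"
        )
    if channel_names is not None:
        names = list(channel_names)
    elif names is None or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(voxels=data, voxel_size_um=voxel_size, channel_names=names)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with voxel-size metadata.

    The OME UUID is derived from the voxel content so identical stacks
    produce byte-identical files (reproducible pipeline runs).
    """
    import hashlib
    import uuid

    z, y, x = stack.voxel_size_um
    digest = hashlib.sha256(np.ascontiguousarray(stack.voxels).tobytes()).digest()
    stable_uuid = uuid.UUID(bytes=digest[:16], version=4)
    tifffile.imwrite(
        path,
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            "UUID": f"urn:uuid:{stable_uuid}",
            "Creator": "gliometry",
            "PhysicalSizeZ": z,
            "PhysicalSizeY": y,
            "PhysicalSizeX": x,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": stack.channel_names},
        },
    )


def _to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    axes = axes.upper().replace("S", "C").replace("Q", "Z")
    if data.ndim == 2:
        return data[None, None]
    if data.ndim == 3:
        if "C" in axes and "Z" not in axes:
            order = [axes.index("C"), axes.index("Y"), axes.index("X")]
            return np.transpose(data, order)[:, None]
        return data[None]  # ZYX single channel
    if data.ndim == 4:
        order = [axes.index(a) for a in "CZYX"]
        return np.transpose(data, order)
    raise ValueError(f"cannot interpret {data.ndim}-D image with axes {axes!r}")


def _ome_pixel_sizes(tif: "tifffile.TiffFile") -> tuple[float, float, float] | None:
    ome = tif.ome_metadata
    if not ome:
        return None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    if px is None:
        return None
    try:
        return (
            float(px.attrib["PhysicalSizeZ"]),
            float(px.attrib["PhysicalSizeY"]),
            float(px.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        return None


def _ome_channel_names(tif: "tifffile.TiffFile") -> list[str] | None:
    ome = tif.ome_metadata
    if not ome:
        return None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    names = [c.attrib.get("Name") for c in root.findall(".//ome:Channel", ns)]
    if not names or any(n is None for n in names):
        return None
    return list(names)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# atlas I/O

def read_atlas(
    path: str | Path,
    midline_axis: tuple[float, float],
    pixel_size_um: tuple[float, float] = (0.2, 0.2),
) -> RegionAtlas:
    """Read a 2-D region-label TIFF into a :class:`RegionAtlas`.

    *midline_axis* is normalized to unit length; labels outside the fixed
    septal label set raise a validation error listing the offenders.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such atlas file: {path}")
    labels = tifffile.imread(path)
    if not np.issubdtype(np.asarray(labels).dtype, np.integer):
        raise ValueError("atlas label image must be integer-valued")
    return RegionAtlas(labels=labels, midline_axis=midline_axis, pixel_size_um=pixel_size_um)


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    tifffile.imwrite(path, atlas.labels.astype(np.uint8))
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "midline_axis": list(atlas.midline_axis),
                "pixel_size_um": list(atlas.pixel_size_um),
                "label_map": {str(k): v for k, v in atlas.label_map.items()},
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# tables

def write_table(records: Sequence, path: str | Path, schema: Sequence[str] | None = None) -> None:
    """Write flat records as a UTF-8 CSV with a header row.

    All records must share one field set ('.' decimal separator, one row per
    record). An empty sequence requires an explicit *schema* for the header.
    """
    import csv

    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in records]
    if not rows:
        if schema is None:
            raise ValueError("empty record sequence requires an explicit schema")
        fields = list(schema)
    else:
        fields = list(rows[0].keys())
        for i, r in enumerate(rows):
            if list(r.keys()) != fields:
                raise ValueError(
                    f"record {i} fields {sorted(r)} differ from first record fields {sorted(fields)}"
                )

    def fmt(v):
        # repr round-trips floats exactly; everything else as str
        if isinstance(v, float) or isinstance(v, np.floating):
            return repr(float(v))
        return v

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for r in rows:
            writer.writerow([fmt(r[f]) for f in fields])
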