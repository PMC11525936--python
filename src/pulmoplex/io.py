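"""Containers and file I/O for multiplexed-imaging artifacts.

Images travel as multipage TIFF (one page per channel, channel names and
pixel size embedded as JSON in the image description), cell tables as CSV,
and regions of interest as GeoJSON-style polygon files in micrometre
coordinates.  Proprietary acquisition formats are out of scope: users
convert to plain TIFF first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, shape, mapping

__all__ = [
    "MultiplexImage",
    "RegionSet",
    "REGION_ROLES",
    "REQUIRED_TABLE_COLUMNS",
    "read_multichannel_image",
    "write_multichannel_image",
    "read_label_mask",
    "write_label_mask",
    "read_cell_table",
    "write_cell_table",
    "read_regions",
    "write_regions",
]

REGION_ROLES = frozenset({
    "include", "exclude",
    "airway-small-SOX2", "airway-large-SOX2", "airway-SOX9",
    "artery-immune-selection",
})

#: columns every cell table must carry (marker columns come on top)
REQUIRED_TABLE_COLUMNS = ("cell_id", "x_um", "y_um")


@dataclass
class MultiplexImage:
    """Channel-stacked intensity raster with named channels.

    data is C x H x W; ``pixel_size_um`` converts pixel to physical
    coordinates (x along columns, y along rows, origin top-left).
    """

    channels: list
    data: np.ndarray
    pixel_size_um: float = 0.51

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("image data must be C x H x W")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel-count mismatch: {len(self.channels)} names for "
                f"{self.data.shape[0]} planes"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("image contains NaN/Inf")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in image (have {self.channels})") from None

    @property
    def shape(self):
        return self.data.shape


@dataclass
class RegionSet:
    """Named polygons (micrometre coordinates) with roles from a closed
    vocabulary; replaces the interactive region selections of the original
    workflow with portable files."""

    regions: list = dc_field(default_factory=list)  # dicts: name, role, polygon

    def __post_init__(self) -> None:
        for r in self.regions:
            if r["role"] not in REGION_ROLES:
                raise ValueError(f"unknown region role {r['role']!r} (region {r['name']!r})")
            if not r["polygon"].is_simple:
                raise ValueError(f"region {r['name']!r}: polygon is self-intersecting")

    def with_role(self, role: str) -> list:
        return [r for r in self.regions if r["role"] == role]

    def __len__(self) -> int:
        return len(self.regions)

    @staticmethod
    def from_polygons(items) -> "RegionSet":
        regs = [{"name": n, "role": role, "polygon": Polygon(coords)}
                for (n, role, coords) in items]
        return RegionSet(regs)


def write_multichannel_image(path, image: MultiplexImage) -> None:
    meta = {"channels": list(image.channels), "pixel_size_um": image.pixel_size_um}
    tifffile.imwrite(path, image.data, description=json.dumps(meta),
                     photometric="minisblack")


def read_multichannel_image(path, channel_names=None, pixel_size_um=None) -> MultiplexImage:
    """Read a TIFF stack; channel names from embedded metadata or the
    supplied list (which must match the page count)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    if data.ndim == 2:
        data = data[None]
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    names = channel_names or meta.get("channels")
    if names is None:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"channel-count mismatch: file has {data.shape[0]} planes, "
            f"got {len(names)} names {list(names)}"
        )
    px = pixel_size_um or meta.get("pixel_size_um") or 0.51
    return MultiplexImage(channels=list(names), data=data, pixel_size_um=px)


def write_label_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_cell_table(path, table: pd.DataFrame) -> None:
    _check_required(table)
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _check_required(table)
    return table


def _check_required(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing required column(s): {', '.join(missing)}")


def write_regions(path, regions: RegionSet) -> None:
    features = [{
        "type": "Feature",
        "properties": {"name": r["name"], "role": r["role"]},
        "geometry": mapping(r["polygon"]),
    } for r in regions.regions]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_regions(path) -> RegionSet:
    with open(path) as fh:
        gj = json.load(fh)
    regs = [{
        "name": f["properties"]["name"],
        "role": f["properties"]["role"],
        "polygon": shape(f["geometry"]),
    } for f in gj.get("features", [])]
    return RegionSet(regs)
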