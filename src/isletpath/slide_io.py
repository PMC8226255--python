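"""Reading and writing the formats the pipeline touches.

A :class:`Slide` is the in-memory stand-in for a scanned multichannel
fluorescence image: a ``(C, H, W)`` array of nonnegative intensities plus the
microns-per-pixel calibration (``mpp``) and a marker → channel map.  All
downstream geometry is expressed in physical units (µm for lengths, mm² for
areas) using the pixel-center convention: pixel ``(row, col)`` has its center
at ``((col + 0.5) * mpp, (row + 0.5) * mpp)`` in (x, y) µm.

Measurement tables (one row per annotation or detection, units encoded in the
column names) are plain CSV; object geometries go out as GeoJSON in µm
coordinates so any digital-pathology viewer can load them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
import tifffile

__all__ = [
    "Slide",
    "read_slide",
    "write_slide",
    "write_measurements",
    "read_measurements",
    "write_objects_geojson",
    "read_objects_geojson",
]


@dataclass
class Slide:
    """Multichannel image with physical calibration.

    pixels : float32 array, shape (n_channels, height, width)
    mpp : microns per pixel (> 0)
    channel_map : marker name → channel index
    """

    pixels: np.ndarray
    mpp: float
    channel_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (C, H, W) array")
        if not self.mpp > 0:
            raise ValueError("mpp must be > 0 (physical units are mandatory)")
        for name, idx in self.channel_map.items():
            if not 0 <= idx < self.pixels.shape[0]:
                raise ValueError(f"channel {name!r} maps to index {idx} "
                                 f"but slide has {self.pixels.shape[0]} channels")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[1:]

    @property
    def markers(self) -> list[str]:
        return list(self.channel_map)

    def channel(self, marker: str) -> np.ndarray:
        """2D intensity image for a marker."""
        if marker not in self.channel_map:
            raise KeyError(f"marker {marker!r} not in channel map "
                           f"{sorted(self.channel_map)}")
        return self.pixels[self.channel_map[marker]]

    def mean_image(self) -> np.ndarray:
        """Unweighted mean over all channels (tissue-thresholder input)."""
        return self.pixels.mean(axis=0)


def write_slide(slide: Slide, path: str | Path) -> Path:
    """Write one TIFF page per channel with mpp in the resolution tags.

    Resolution is stored as pixels-per-centimeter so that any reader using
    the baseline TIFF tags recovers ``mpp = 1e4 / resolution``.
    """
    path = Path(path)
    px_per_cm = 1e4 / slide.mpp
    meta = {"channels": {m: i for m, i in slide.channel_map.items()},
            "mpp_um": slide.mpp}
    with tifffile.TiffWriter(path) as tif:
        for c in range(slide.n_channels):
            tif.write(
                slide.pixels[c].astype(np.float32),
                resolution=(px_per_cm, px_per_cm),
                resolutionunit="CENTIMETER",
                description=json.dumps(meta) if c == 0 else None,
            )
    return path


def _mpp_from_page(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value
    # 2 = inch, 3 = centimeter (TIFF baseline)
    unit_um = {2: 25_400.0, 3: 10_000.0}.get(int(unit))
    if unit_um is None:
        return None
    return unit_um * den / num


def read_slide(path: str | Path,
               channel_map: dict[str, int] | None = None,
               mpp_override: float | None = None) -> Slide:
    """Read a flat/multipage TIFF into a :class:`Slide`.

    The channel map is taken from the embedded JSON description when present,
    unless ``channel_map`` is given.  A missing mpp with no override is a hard
    error: every downstream statistic is in physical units.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        if len(pages) == 0:
            raise ValueError(f"{path}: empty TIFF")
        arr = np.stack([p.asarray() for p in pages]).astype(np.float32)
        mpp = mpp_override if mpp_override is not None else _mpp_from_page(pages[0])
        desc = pages[0].tags.get("ImageDescription")
        if channel_map is None and desc is not None:
            try:
                meta = json.loads(desc.value)
                channel_map = {str(k): int(v) for k, v in meta["channels"].items()}
            except (json.JSONDecodeError, KeyError, TypeError):
                channel_map = None
    if mpp is None:
        raise ValueError(f"{path}: no resolution metadata and no mpp_override; "
                         "physical units are mandatory")
    return Slide(pixels=arr, mpp=float(mpp), channel_map=channel_map or {})


def write_measurements(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a measurement table as UTF-8 comma-separated CSV.

    No thousands separators, '.' decimal point; column names (which carry the
    units, e.g. ``"CD45+/mm^2"``) are preserved verbatim.  Floats use repr
    precision so a round-trip preserves values to better than 1e-9 relative.
    """
    path = Path(path)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def _as_valid(geom, oid):
    if geom.is_valid:
        return geom
    from shapely.validation import make_valid
    fixed = make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        polys = []
        for g in fixed.geoms:
            if g.geom_type == "Polygon":
                polys.append(g)
            elif g.geom_type == "MultiPolygon":
                polys.extend(g.geoms)
        fixed = sgeom.MultiPolygon(polys) if len(polys) != 1 else polys[0]
    if fixed.is_empty or not fixed.is_valid:
        raise ValueError(f"object {oid!r}: invalid geometry could not be repaired")
    return fixed


def write_objects_geojson(islets, cells, path: str | Path,
                          extra_features: list[dict] | None = None) -> Path:
    """Export islet polygons and cell points as one GeoJSON FeatureCollection.

    Coordinates are in µm.  Invalid polygons are repaired with a zero-width
    buffer; irreparable ones are rejected with their object id.

    ``islets`` is an iterable of objects with ``id``/``polygon`` attributes
    (or ``(id, polygon, properties)`` tuples); ``cells`` is an iterable of
    ``(id, (x_um, y_um), properties)``.
    """
    features = []
    for islet in islets:
        if isinstance(islet, tuple):
            oid, poly, props = islet
        else:
            oid, poly = islet.id, islet.polygon
            props = {"classification": "Islet",
                     "n_cells": getattr(islet, "n_cells", None)}
        poly = _as_valid(poly, oid)
        features.append({
            "type": "Feature",
            "id": oid,
            "geometry": sgeom.mapping(poly),
            "properties": {"object_type": "annotation", **props},
        })
    for oid, (x, y), props in cells:
        features.append({
            "type": "Feature",
            "id": oid,
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"object_type": "detection", **props},
        })
    if extra_features:
        features.extend(extra_features)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_objects_geojson(path: str | Path):
    """Load a FeatureCollection back as (features, shapely geometries)."""
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    geoms = [sgeom.shape(f["geometry"]) for f in fc["features"]]
    return fc["features"], geoms
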