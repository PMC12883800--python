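"""Raster and vector I/O for the FSC change-detection pipeline.

Rasters are multi-band float32 GeoTIFFs (one file per epoch) written and read
with :mod:`tifffile`; georeferencing is carried in the standard GeoTIFF
``ModelPixelScale``/``ModelTiepoint`` tags and a JSON ``ImageDescription``
holding band names, nodata value, CRS identifier and epoch label.  Vector
layers (forest sub-compartment polygons) are GeoJSON feature collections read
into :class:`shapely` geometries.

Pixel convention: row/col, 0-based, pixel-center registration, north-up grid.
Map coordinates of pixel ``(r, c)`` are ``(x0 + (c + 0.5)·ps, y0 − (r + 0.5)·ps)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: Fixed vegetation cover type order used everywhere (label encoding and
#: argmax tie-breaking depend on it).
CLASS_ORDER = ("Arbor", "Shrub", "Bamboo", "Bare", "Other")

#: Sentinel-2 band order used throughout the pipeline.
ALL_BANDS = ("B2", "B3", "B4", "B8", "B11", "B12")
#: Bands that must be present for the spectral feature set.
REQUIRED_BANDS = ("B2", "B3", "B4", "B8")

NODATA = -9999.0

#: CRS identifiers that are geographic (degree-based) and therefore rejected:
#: the 3,000 m² training-area filter needs a meter-based projected CRS.
_GEOGRAPHIC_CRS = {"EPSG:4326", "EPSG:4269", "EPSG:4258", "WGS84", "CRS84"}

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

REFLECTANCE_RANGE = (-0.1, 1.5)


@dataclass(frozen=True)
class GridTransform:
    """Affine georeferencing for an axis-aligned, north-up grid.

    Parameters are the map coordinates of the raster's top-left corner and
    the (square) pixel size in map units (meters).
    """

    x_origin: float
    y_origin: float
    pixel_size: float

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of pixel ``(row, col)``."""
        x = self.x_origin + (col + 0.5) * self.pixel_size
        y = self.y_origin - (row + 0.5) * self.pixel_size
        return x, y

    def to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Nearest pixel (by center) to a map coordinate.

        Ties (coordinate exactly between two pixel centers) break toward the
        smaller index so patch windows are bit-reproducible.
        """
        fc = (x - self.x_origin) / self.pixel_size - 0.5
        fr = (self.y_origin - y) / self.pixel_size - 0.5
        # round-half-down == ceil(v - 1/2)
        return int(math.ceil(fr - 0.5)), int(math.ceil(fc - 0.5))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x_origin, self.y_origin, self.pixel_size)


@dataclass
class MultispectralScene:
    """One epoch of co-registered multispectral reflectance bands."""

    band_stack: np.ndarray  # (rows, cols, nbands) float32
    band_names: tuple[str, ...]
    transform: GridTransform
    crs_id: str
    nodata_mask: np.ndarray  # (rows, cols) bool, True where nodata
    epoch: str
    validation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.band_names)) != len(self.band_names):
            raise FormatError("duplicate band names: %r" % (self.band_names,))
        if self.band_stack.ndim != 3 or self.band_stack.shape[2] != len(self.band_names):
            raise FormatError(
                "band_stack shape %r does not match %d band names"
                % (self.band_stack.shape, len(self.band_names))
            )
        if self.nodata_mask.shape != self.band_stack.shape[:2]:
            raise FormatError("nodata mask shape does not match raster shape")
        if self.transform.pixel_size <= 0:
            raise FormatError("pixel size must be positive (non-invertible transform)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.band_stack.shape[:2]

    def band(self, name: str) -> np.ndarray:
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise FormatError(f"band {name!r} not present in scene") from None
        return self.band_stack[:, :, idx]


@dataclass
class FSCRecord:
    """A forest sub-compartment: polygon unit of the forest inventory."""

    fsc_id: str
    geometry: BaseGeometry
    area_m2: float
    class_by_epoch: dict[str, str | None] = field(default_factory=dict)

    def label(self, epoch: str) -> str | None:
        return self.class_by_epoch.get(epoch)


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def write_scene(scene: MultispectralScene, path) -> None:
    """Write a scene as a multi-band float32 GeoTIFF.

    Nodata pixels are stored as the sentinel value −9999 in every band.
    """
    data = np.moveaxis(scene.band_stack.astype(np.float32), 2, 0).copy()
    data[:, scene.nodata_mask] = NODATA
    meta = {
        "band_names": list(scene.band_names),
        "nodata": NODATA,
        "transform": scene.transform.as_tuple(),
        "crs_id": scene.crs_id,
        "epoch": scene.epoch,
    }
    ps = scene.transform.pixel_size
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
        (
            _MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, scene.transform.x_origin, scene.transform.y_origin, 0.0),
        ),
    ]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=extratags,
    )


def read_scene(path, epoch: str | None = None, swir_path=None) -> MultispectralScene:
    """Read a multi-band GeoTIFF written by :func:`write_scene`.

    Parameters
    ----------
    path
        GeoTIFF with ≥4 bands and a JSON description naming them.
    epoch
        Epoch label; defaults to the label stored in the file.
    swir_path
        Optional supplementary GeoTIFF holding B11/B12 at native 20 m
        resolution; it is upsampled ×2 by nearest neighbor and appended.

    Out-of-range reflectance values (outside [−0.1, 1.5]) are counted in the
    returned scene's ``validation`` report rather than rejected.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        raise FormatError(f"{path}: missing or malformed JSON band metadata")
    band_names = tuple(meta["band_names"])
    for required in REQUIRED_BANDS:
        if required not in band_names:
            raise FormatError(f"{path}: required band {required!r} is missing")
    crs_id = str(meta.get("crs_id", ""))
    if crs_id.upper() in _GEOGRAPHIC_CRS:
        raise FormatError(
            f"{path}: CRS {crs_id} is geographic; a meter-based projected CRS "
            "is required for area-based filtering"
        )
    if data.ndim == 2:
        data = data[None, :, :]
    stack = np.moveaxis(data, 0, 2).astype(np.float32)

    if swir_path is not None:
        with tifffile.TiffFile(swir_path) as tif:
            sdata = tif.asarray()
            smeta = json.loads(tif.pages[0].description)
        if sdata.ndim == 2:
            sdata = sdata[None, :, :]
        sdata = np.repeat(np.repeat(sdata, 2, axis=1), 2, axis=2)
        sdata = sdata[:, : stack.shape[0], : stack.shape[1]]
        stack = np.concatenate([stack, np.moveaxis(sdata, 0, 2)], axis=2)
        band_names = band_names + tuple(smeta["band_names"])

    nodata = float(meta.get("nodata", NODATA))
    mask = np.any(stack == nodata, axis=2)
    stack = np.where(mask[:, :, None], np.float32(nodata), stack)

    x0, y0, ps = meta["transform"]
    valid = stack[~mask]
    lo, hi = REFLECTANCE_RANGE
    n_oor = int(np.sum((valid < lo) | (valid > hi)))
    validation = {"out_of_range_values": n_oor}
    if n_oor:
        logger.warning("%s: %d reflectance values outside %s", path, n_oor, REFLECTANCE_RANGE)
    return MultispectralScene(
        band_stack=stack,
        band_names=band_names,
        transform=GridTransform(x0, y0, ps),
        crs_id=crs_id,
        nodata_mask=mask,
        epoch=epoch if epoch is not None else str(meta.get("epoch", "")),
        validation=validation,
    )


# ---------------------------------------------------------------------------
# Vector I/O
# ---------------------------------------------------------------------------

def write_fsc_layer(records: list[FSCRecord], path, crs_id: str = "") -> None:
    """Write FSC polygons as a GeoJSON FeatureCollection."""
    features = []
    for rec in records:
        props = {"fsc_id": rec.fsc_id, "area_m2": rec.area_m2}
        for ep, label in rec.class_by_epoch.items():
            props[f"class_{ep}"] = label
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(rec.geometry),
                "properties": props,
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if crs_id:
        collection["crs"] = {"type": "name", "properties": {"name": crs_id}}
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_fsc_layer(path, report: list | None = None) -> list[FSCRecord]:
    """Read FSC polygons from GeoJSON.

    Invalid geometries are repaired by zero-width buffering; geometries that
    cannot be repaired are rejected.  Records whose stored ``area_m2``
    deviates more than 1% from the geometry's computed area get a validation
    warning.  Every repair/rejection/warning is logged and, if ``report`` is
    given, appended to it as a ``(fsc_id, kind, message)`` tuple.
    """
    if report is None:
        report = []
    with open(path) as fh:
        collection = json.load(fh)
    records: list[FSCRecord] = []
    for feat in collection.get("features", []):
        props = feat.get("properties", {})
        if "fsc_id" not in props:
            raise FormatError(f"{path}: feature without required property 'fsc_id'")
        fsc_id = str(props["fsc_id"])
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            reason = explain_validity(geom)
            repaired = geom.buffer(0)
            if repaired.is_valid and not repaired.is_empty:
                report.append((fsc_id, "repaired", reason))
                logger.warning("FSC %s: invalid geometry repaired (%s)", fsc_id, reason)
                geom = repaired
            else:
                report.append((fsc_id, "rejected", reason))
                logger.warning("FSC %s: invalid geometry rejected (%s)", fsc_id, reason)
                continue
        area = float(props.get("area_m2", geom.area))
        if geom.area > 0 and abs(area - geom.area) / geom.area > 0.01:
            msg = f"stored area {area:.1f} deviates >1% from geometry area {geom.area:.1f}"
            report.append((fsc_id, "area_mismatch", msg))
            logger.warning("FSC %s: %s", fsc_id, msg)
        class_by_epoch = {
            key[len("class_"):]: value
            for key, value in props.items()
            if key.startswith("class_")
        }
        records.append(
            FSCRecord(
                fsc_id=fsc_id,
                geometry=geom,
                area_m2=area,
                class_by_epoch=class_by_epoch,
            )
        )
    return records
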