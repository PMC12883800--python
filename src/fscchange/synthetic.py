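"""Synthetic two-epoch multispectral scenes with known FSC labels.

The real inventory data this pipeline was designed for (forest sub-compartment
polygons with surveyed vegetation cover types, plus growing-season Sentinel-2
composites) are not publicly available, so this module generates scenes with
the same statistical structure: an irregular polygon tessellation with a
heavy-tailed area distribution, five vegetation cover types with distinct
band-reflectance signatures and distinct spatial texture, and a configurable
fraction of polygons whose cover type changes between the two epochs.

Construction:

* FSC boundaries are Voronoi cells of seed points placed on distinct pixel
  centers.  Seed density mixes a spatial gradient with a few tight clusters,
  which yields single-pixel cells inside clusters and very large cells in the
  sparse corner — an area distribution spanning several orders of magnitude,
  as in real sub-compartment layers.
* Per-class reflectance is the class signature mean plus spatially correlated
  Gaussian noise (white noise smoothed at the class's ``texture_scale`` and
  rescaled to unit variance), so classes differ in their co-occurrence
  texture as well as their spectra.
* Injected changes are drawn uniformly among FSCs above the 3,000 m² training
  threshold, with the new label uniform over the other four classes, so that
  every injected change is in principle learnable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box

from .exceptions import ConfigError
from .geo_io import (
    ALL_BANDS,
    CLASS_ORDER,
    FSCRecord,
    GridTransform,
    MultispectralScene,
    write_fsc_layer,
    write_scene,
)

#: Area threshold (m²) above which FSCs are training-eligible and may receive
#: an injected change.
TRAINING_AREA_M2 = 3000.0

DEFAULT_CRS = "EPSG:32648"  # UTM zone 48N — meter-based, covers Sichuan

#: Training-sample class composition: counts 1803/1645/574/30/58 rebalanced
#: from the raw inventory (which is ~94% Arbor) to avoid extreme imbalance.
DEFAULT_PROPORTIONS = (1803 / 4110, 1645 / 4110, 574 / 4110, 30 / 4110, 58 / 4110)


@dataclass(frozen=True)
class ClassSignature:
    """Spectral and textural signature of one vegetation cover type.

    ``band_means`` are surface reflectances in [0, 1] for (B2, B3, B4, B8,
    B11, B12).  ``band_sd`` is the per-pixel standard deviation of the
    fine-scale additive noise at the default scene noise level;
    ``texture_scale`` is its correlation length in pixels, which controls
    the class's co-occurrence texture (small scale → rough, large →
    smooth).  ``brightness_gain`` scales the class's response to the
    scene-wide multiplicative brightness field (terrain illumination,
    canopy density): that field moves all bands proportionally, so raw band
    values vary strongly within a class while ratio-type vegetation indices
    stay nearly constant — the structure that makes index features
    genuinely informative beyond the raw bands.
    """

    class_label: str
    band_means: tuple[float, ...]
    band_sd: float
    texture_scale: float
    brightness_gain: float = 0.2

    def __post_init__(self) -> None:
        means = dict(zip(ALL_BANDS, self.band_means))
        if not all(0.0 <= m <= 1.0 for m in self.band_means):
            raise ConfigError(f"{self.class_label}: band means must lie in [0, 1]")
        if self.class_label in ("Arbor", "Shrub", "Bamboo") and means["B8"] <= means["B4"]:
            raise ConfigError(f"{self.class_label}: vegetation requires B8 mean > B4 mean")
        if self.class_label == "Bare" and means["B4"] < means["B8"]:
            raise ConfigError("Bare: requires B4 mean >= B8 mean")


#: Default signatures.  Vegetation classes have the strong red-edge contrast
#: (B8 ≫ B4) of healthy canopies; Bare has the flat, bright soil spectrum with
#: B4 ≥ B8.  Arbor canopies are spatially smooth (large texture_scale); bamboo
#: stands and bare ground are fine-grained.  Neighboring classes overlap
#: deliberately: Arbor/Bamboo are close in their index ratios and are mainly
#: separated by texture, Shrub/Other mainly by their indices, and the ±20–30%
#: brightness swings overlap all raw-band distributions, so classification is
#: realistic rather than trivially separable.
DEFAULT_SIGNATURES: dict[str, ClassSignature] = {
    "Arbor": ClassSignature("Arbor", (0.030, 0.055, 0.040, 0.420, 0.180, 0.090), 0.018, 2.5, 0.20),
    "Shrub": ClassSignature("Shrub", (0.040, 0.070, 0.062, 0.340, 0.225, 0.125), 0.020, 1.3, 0.22),
    "Bamboo": ClassSignature("Bamboo", (0.034, 0.070, 0.050, 0.400, 0.185, 0.095), 0.020, 0.6, 0.20),
    "Bare": ClassSignature("Bare", (0.110, 0.150, 0.210, 0.200, 0.300, 0.280), 0.030, 0.4, 0.30),
    "Other": ClassSignature("Other", (0.046, 0.082, 0.078, 0.300, 0.245, 0.150), 0.022, 1.0, 0.25),
}

_DEFAULT_NOISE_SD = 0.025


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic two-epoch scene pair."""

    grid_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 10.0
    n_fsc: int = 400
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    change_fraction: float = 0.1
    #: Global noise level in reflectance units; each class's realized pixel
    #: standard deviation is ``signature.band_sd × noise_sd / 0.025`` so the
    #: default reproduces the signatures' own band_sd exactly and
    #: ``noise_sd → 0`` removes all noise.
    noise_sd: float = _DEFAULT_NOISE_SD
    #: Correlation length (pixels) of the scene-wide multiplicative
    #: brightness field (illumination/terrain shading); spans polygon
    #: boundaries and is drawn anew per epoch.
    brightness_scale_px: float = 10.0
    seed: int = 0
    epoch_labels: tuple[str, str] = ("e1", "e2")
    n_nodata_holes: int = 0
    hole_size_px: int = 8
    signatures: dict[str, ClassSignature] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if len(self.class_proportions) != len(CLASS_ORDER):
            raise ConfigError("class_proportions must have one entry per class")
        if any(p < 0 for p in self.class_proportions):
            raise ConfigError("class_proportions must be nonnegative")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigError("class_proportions must sum to 1")
        if not 0.0 <= self.change_fraction <= 1.0:
            raise ConfigError("change_fraction must lie in [0, 1]")
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ConfigError("grid_shape must be positive")
        if self.n_fsc < 1:
            raise ConfigError("n_fsc must be >= 1")


# ---------------------------------------------------------------------------
# Seed placement and tessellation
# ---------------------------------------------------------------------------

def _seed_pixels(rng: np.random.Generator, rows: int, cols: int, n: int) -> np.ndarray:
    """Choose ``n`` distinct pixel centers as Voronoi seeds.

    The sampling weight combines a left-to-right density gradient (sparse on
    the left → a few very large cells) with a few tight Gaussian clusters
    (→ many near-single-pixel cells), giving the heavy-tailed area
    distribution of real sub-compartment layers.  Distinct pixels guarantee
    every seed owns at least its own pixel.
    """
    npix = rows * cols
    if n > npix:
        raise ConfigError(
            f"n_fsc={n} exceeds the number of pixels ({npix}); polygons would "
            "fall below 1 pixel"
        )
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    weight = (0.15 + cc / max(cols - 1, 1)) ** 3
    n_clusters = 3 if n >= 30 else 0
    if n_clusters:
        sd = max(1.5, 0.01 * min(rows, cols))
        for _ in range(n_clusters):
            cr = rng.uniform(0.2 * rows, 0.8 * rows)
            ccol = rng.uniform(0.4 * cols, 0.9 * cols)
            bump = np.exp(-((rr - cr) ** 2 + (cc - ccol) ** 2) / (2 * sd**2))
            # each cluster carries roughly a quarter of the total seed mass
            weight = weight + bump * weight.sum() / (4 * 2 * np.pi * sd**2)
    p = (weight / weight.sum()).ravel()
    flat = rng.choice(npix, size=n, replace=False, p=p)
    return np.stack([flat // cols, flat % cols], axis=1)  # (n, 2) row, col


def _voronoi_polygons(seeds_xy: np.ndarray, bounds: tuple[float, float, float, float]) -> list[Polygon]:
    """Voronoi cells of ``seeds_xy`` clipped to a rectangular boundary.

    Distant mirror points make every real region finite before clipping.
    """
    minx, miny, maxx, maxy = bounds
    span = max(maxx - minx, maxy - miny)
    cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
    far = 10 * span
    dummies = np.array(
        [[cx - far, cy], [cx + far, cy], [cx, cy - far], [cx, cy + far]]
    )
    vor = Voronoi(np.vstack([seeds_xy, dummies]))
    clip = box(minx, miny, maxx, maxy)
    polys: list[Polygon] = []
    for i in range(len(seeds_xy)):
        region = vor.regions[vor.point_region[i]]
        cell = Polygon(vor.vertices[region])
        polys.append(cell.intersection(clip))
    return polys


def _allocate_labels(rng: np.random.Generator, n: int, proportions) -> np.ndarray:
    """Deterministic largest-remainder allocation of class counts, shuffled."""
    props = np.asarray(proportions, dtype=float)
    counts = np.floor(props * n).astype(int)
    remainder = props * n - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    labels = np.repeat(np.arange(len(props)), counts)
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# Scene synthesis
# ---------------------------------------------------------------------------

def _render_epoch(
    rng: np.random.Generator,
    config: SceneConfig,
    owner_map: np.ndarray,
    class_idx: np.ndarray,
    nodata_mask: np.ndarray,
    epoch: str,
    transform: GridTransform,
) -> MultispectralScene:
    rows, cols = config.grid_shape
    nbands = len(ALL_BANDS)
    stack = np.zeros((rows, cols, nbands), dtype=np.float32)
    class_map = class_idx[owner_map]
    noise_scale = config.noise_sd / _DEFAULT_NOISE_SD

    # scene-wide multiplicative brightness field, unit variance, new per epoch
    bright = gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=config.brightness_scale_px,
        mode="reflect",
    )
    bstd = bright.std()
    bright = bright / bstd if bstd > 0 else np.zeros_like(bright)

    for k, name in enumerate(CLASS_ORDER):
        sig = config.signatures[name]
        mask = class_map == k
        sd = sig.band_sd * noise_scale
        gain = sig.brightness_gain * noise_scale
        for b in range(nbands):
            # fine-scale additive noise, renormalized so the realized pixel
            # sd is `sd` regardless of the smoothing scale
            white = rng.standard_normal((rows, cols))
            fld = gaussian_filter(white, sigma=sig.texture_scale, mode="reflect")
            fstd = fld.std()
            if fstd > 0 and sd > 0:
                fld *= sd / fstd
            else:
                fld[:] = 0.0
            if mask.any():
                stack[mask, b] = (
                    sig.band_means[b] * (1.0 + gain * bright[mask]) + fld[mask]
                )
    np.clip(stack, 0.0, 1.0, out=stack)
    return MultispectralScene(
        band_stack=stack,
        band_names=ALL_BANDS,
        transform=transform,
        crs_id=config.crs_id,
        nodata_mask=nodata_mask.copy(),
        epoch=epoch,
    )


def generate_scene_pair(
    config: SceneConfig,
) -> tuple[MultispectralScene, MultispectralScene, list[FSCRecord]]:
    """Generate a two-epoch scene pair with known labels and injected changes.

    Returns the two scenes and one :class:`FSCRecord` per polygon carrying
    labels for both epochs.  Identical configs (including seed) give
    bit-identical output.  Exactly ``round(change_fraction × n_fsc)`` FSCs
    change label between the epochs, all of them above the 3,000 m² training
    threshold.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    ps = config.pixel_size
    transform = GridTransform(x_origin=500_000.0, y_origin=3_500_000.0, pixel_size=ps)

    seed_rc = _seed_pixels(rng, rows, cols, config.n_fsc)
    seeds_xy = np.array([transform.pixel_center(r, c) for r, c in seed_rc])

    # pixel ownership: nearest seed == exact Voronoi assignment
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    px = transform.x_origin + (cc + 0.5) * ps
    py = transform.y_origin - (rr + 0.5) * ps
    _, owner = cKDTree(seeds_xy).query(np.stack([px.ravel(), py.ravel()], axis=1))
    owner_map = owner.reshape(rows, cols)

    bounds = (
        transform.x_origin,
        transform.y_origin - rows * ps,
        transform.x_origin + cols * ps,
        transform.y_origin,
    )
    polys = _voronoi_polygons(seeds_xy, bounds)

    labels_e1 = _allocate_labels(rng, config.n_fsc, config.class_proportions)
    labels_e2 = labels_e1.copy()

    areas = np.array([p.area for p in polys])
    n_changes = int(round(config.change_fraction * config.n_fsc))
    eligible = np.flatnonzero(areas > TRAINING_AREA_M2)
    if n_changes > len(eligible):
        raise ConfigError(
            f"cannot inject {n_changes} changes: only {len(eligible)} FSCs "
            f"exceed the {TRAINING_AREA_M2:.0f} m² threshold"
        )
    changed = rng.choice(eligible, size=n_changes, replace=False)
    for i in changed:
        others = [k for k in range(len(CLASS_ORDER)) if k != labels_e1[i]]
        labels_e2[i] = others[rng.integers(len(others))]

    nodata_mask = np.zeros((rows, cols), dtype=bool)
    for _ in range(config.n_nodata_holes):
        h = min(config.hole_size_px, rows, cols)
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - h + 1))
        nodata_mask[r0 : r0 + h, c0 : c0 + h] = True

    e1, e2 = config.epoch_labels
    scene1 = _render_epoch(rng, config, owner_map, labels_e1, nodata_mask, e1, transform)
    scene2 = _render_epoch(rng, config, owner_map, labels_e2, nodata_mask, e2, transform)

    records = [
        FSCRecord(
            fsc_id=f"fsc{i:05d}",
            geometry=polys[i],
            area_m2=float(areas[i]),
            class_by_epoch={e1: CLASS_ORDER[labels_e1[i]], e2: CLASS_ORDER[labels_e2[i]]},
        )
        for i in range(config.n_fsc)
    ]
    return scene1, scene2, records


def scene_to_files(
    scene1: MultispectralScene,
    scene2: MultispectralScene,
    records: list[FSCRecord],
    directory,
) -> dict[str, Path]:
    """Write the scene pair, polygon layer and label table to a directory.

    Returns a mapping of artifact name → path.  Round-trip reads reproduce
    band values exactly (float32) and polygon areas to within 1e-6 relative.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "raster_e1": directory / f"scene_{scene1.epoch}.tif",
        "raster_e2": directory / f"scene_{scene2.epoch}.tif",
        "fsc_layer": directory / "fsc.geojson",
        "labels": directory / "labels.csv",
    }
    write_scene(scene1, paths["raster_e1"])
    write_scene(scene2, paths["raster_e2"])
    write_fsc_layer(records, paths["fsc_layer"], crs_id=scene1.crs_id)
    epochs = sorted({ep for rec in records for ep in rec.class_by_epoch})
    with open(paths["labels"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fsc_id", "area_m2"] + [f"class_{ep}" for ep in epochs])
        for rec in records:
            writer.writerow(
                [rec.fsc_id, f"{rec.area_m2:.6f}"]
                + [rec.class_by_epoch.get(ep, "") for ep in epochs]
            )
    return paths


def small_scene_config(**overrides) -> SceneConfig:
    """A small, fast configuration used by examples and tests."""
    defaults = dict(grid_shape=(96, 96), n_fsc=60, change_fraction=0.1, seed=0)
    defaults.update(overrides)
    return SceneConfig(**defaults)
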