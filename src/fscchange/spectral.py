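"""Per-patch spectral band summaries and vegetation indices.

Ten standard vegetation/land-cover indices are computed from the patch band
means.  Formulas (surface reflectance; B2=blue, B3=green, B4=red, B8=NIR,
B11/B12=SWIR):

====== =============================================
NDVI   (B8 − B4) / (B8 + B4)
EVI    2.5 (B8 − B4) / (B8 + 6·B4 − 7.5·B2 + 1)
NBRI   (B8 − B12) / (B8 + B12)
SAVI   1.5 (B8 − B4) / (B8 + B4 + 0.5)
RVI    B8 / B4
DVI    B8 − B4
NDBI   (B11 − B8) / (B11 + B8)
BGRVI  (B3 − (B2 + B4)) / (B3 + (B2 + B4))
GNDVI  (B8 − B3) / (B8 + B3)
NDWI   (B3 − B8) / (B3 + B8)
====== =============================================

SAVI uses the canonical soil-adjustment factor L = 0.5 with the matching
(1 + L) = 1.5 scaling.  Indices are evaluated on patch band means rather
than per pixel (the two differ for ratio indices); the ``vi_per_pixel``
switch in the pipeline config selects per-pixel evaluation followed by
averaging instead.
"""

from __future__ import annotations

import numpy as np

from .exceptions import FormatError
from .patching import PatchSample

_EPS = 1e-12

#: name → (formula, required bands)
VI_FORMULAS = {
    "NDVI": (lambda b: _nd(b["B8"], b["B4"]), ("B8", "B4")),
    "EVI": (
        lambda b: _ratio(2.5 * (b["B8"] - b["B4"]), b["B8"] + 6.0 * b["B4"] - 7.5 * b["B2"] + 1.0),
        ("B8", "B4", "B2"),
    ),
    "NBRI": (lambda b: _nd(b["B8"], b["B12"]), ("B8", "B12")),
    "SAVI": (lambda b: _ratio(1.5 * (b["B8"] - b["B4"]), b["B8"] + b["B4"] + 0.5), ("B8", "B4")),
    "RVI": (lambda b: _ratio(b["B8"], b["B4"]), ("B8", "B4")),
    "DVI": (lambda b: b["B8"] - b["B4"], ("B8", "B4")),
    "NDBI": (lambda b: _nd(b["B11"], b["B8"]), ("B11", "B8")),
    "BGRVI": (lambda b: _nd(b["B3"], b["B2"] + b["B4"]), ("B3", "B2", "B4")),
    "GNDVI": (lambda b: _nd(b["B8"], b["B3"]), ("B8", "B3")),
    "NDWI": (lambda b: _nd(b["B3"], b["B8"]), ("B3", "B8")),
}

VI_NAMES = tuple(VI_FORMULAS)


def _ratio(num: float, den: float) -> float:
    """num/den, defined as 0 when the denominator is degenerate."""
    if abs(den) < _EPS:
        return 0.0
    return num / den


def _nd(a: float, b: float) -> float:
    """Normalized difference (a − b)/(a + b)."""
    return _ratio(a - b, a + b)


def band_means(patch: PatchSample, band_names: tuple[str, ...]) -> dict[str, float]:
    """Arithmetic mean over the window pixels, per band."""
    return {
        name: float(np.mean(patch.window[:, :, i]))
        for i, name in enumerate(band_names)
    }


def vegetation_index(name: str, bands: dict[str, float]) -> float:
    """Evaluate one index from band means.

    A denominator smaller than 1e-12 in magnitude yields 0 (degenerate
    input); an unknown index name raises :class:`FormatError`.
    """
    try:
        formula, required = VI_FORMULAS[name]
    except KeyError:
        raise FormatError(f"unknown vegetation index {name!r}") from None
    for band in required:
        if band not in bands:
            raise FormatError(f"index {name} requires band {band}")
    return float(formula(bands))


def available_indices(band_names) -> tuple[str, ...]:
    """Indices computable from the given bands, in canonical order."""
    present = set(band_names)
    return tuple(
        name for name, (_, req) in VI_FORMULAS.items() if present.issuperset(req)
    )


def spectral_features(
    patch: PatchSample,
    band_names: tuple[str, ...],
    indices: tuple[str, ...] | None = None,
    vi_per_pixel: bool = False,
) -> dict[str, float]:
    """Band means plus vegetation indices for one patch.

    With ``vi_per_pixel=True`` each index is evaluated on every window pixel
    and then averaged; the default evaluates on the band means directly.
    """
    means = band_means(patch, band_names)
    if indices is None:
        indices = available_indices(band_names)
    values = dict(means)
    if vi_per_pixel:
        for name in indices:
            per_px = [
                vegetation_index(
                    name,
                    {
                        bn: float(patch.window[r, c, i])
                        for i, bn in enumerate(band_names)
                    },
                )
                for r in range(patch.window.shape[0])
                for c in range(patch.window.shape[1])
            ]
            values[name] = float(np.mean(per_px))
    else:
        for name in indices:
            values[name] = vegetation_index(name, means)
    return values
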