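"""Gray-level co-occurrence texture features.

A window is quantized to ``N`` gray levels between its own min and max,
co-occurrence counts are accumulated at distance 1 over the four standard
angles (0°, 45°, 90°, 135°), symmetrized and normalized to a joint
probability matrix P, and eight Haralick-style metrics are derived:

=====  =====================================================
MEAN   Σᵢⱼ i·P(i,j)
VAR    Σᵢⱼ (i − μ)²·P(i,j)            with μ = MEAN
HOM    Σᵢⱼ P(i,j) / (1 + |i − j|)     (homogeneity / IDM)
CON    Σᵢⱼ |i − j|²·P(i,j)            (contrast)
DIS    Σᵢⱼ |i − j|·P(i,j)             (dissimilarity)
ENT    −Σᵢⱼ P(i,j)·log₂ P(i,j)        (entropy, bits; 0·log 0 = 0)
ENE    Σᵢⱼ P(i,j)²                    (energy / angular second moment)
COR    Σᵢⱼ (i − x̄)(j − ȳ)·P(i,j)/(σₓ·σᵧ)
=====  =====================================================

where x̄, ȳ, σₓ, σᵧ are the row/column marginal means and standard
deviations.  These are the standard definitions; two widely-circulated
variant formulas for VAR (sample-variance-style division by N−1) and DIS
(an extra leading i factor) describe different quantities than the
contrast/heterogeneity measures they are used as, and are not implemented.

The co-occurrence accumulation itself is delegated to
:func:`skimage.feature.graycomatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .patching import PatchSample

DEFAULT_LEVELS = 32
DEFAULT_DISTANCE = 1
#: (row, col) offsets of the standard 4-angle set at distance 1.
DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

METRIC_NAMES = ("MEAN", "VAR", "HOM", "CON", "DIS", "ENT", "ENE", "COR")


@dataclass
class GLCMMatrix:
    """Normalized gray-level co-occurrence matrix."""

    P: np.ndarray  # (N, N), entries sum to 1
    N: int
    offsets: tuple
    symmetric: bool


@dataclass
class TextureMetrics:
    MEAN: float
    VAR: float
    HOM: float
    CON: float
    DIS: float
    ENT: float
    ENE: float
    COR: float
    mu: float
    x_mean: float
    y_mean: float
    sigma_x: float
    sigma_y: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def quantize(window: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Quantize a window to integer gray levels in [0, levels−1].

    Uniform binning between the window minimum and maximum with half-open
    bins (lo, hi]: a value exactly on an interior edge bins low.  A constant
    window maps entirely to level 0.
    """
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    lo, hi = window.min(), window.max()
    if hi == lo:
        return np.zeros(window.shape, dtype=np.uint8)
    t = (window - lo) / (hi - lo) * levels
    q = np.ceil(t).astype(int) - 1
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm(
    quantized: np.ndarray,
    distance: int = DEFAULT_DISTANCE,
    angles: tuple = DEFAULT_ANGLES,
    symmetric: bool = True,
    levels: int | None = None,
) -> GLCMMatrix:
    """Co-occurrence matrix accumulated over all angles and normalized.

    With ``symmetric=True`` each pixel pair is counted in both directions
    before normalization.
    """
    quantized = np.asarray(quantized)
    if quantized.ndim != 2 or quantized.size < 2:
        raise ValueError("window must be 2-D with at least 2 pixels")
    if levels is None:
        levels = int(quantized.max()) + 1
    levels = max(levels, 2)
    if distance >= max(quantized.shape):
        raise ValueError("offset distance exceeds window extent")
    counts = graycomatrix(
        quantized.astype(np.uint8),
        distances=[distance],
        angles=list(angles),
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )
    P = counts[:, :, 0, :].sum(axis=2).astype(float)
    total = P.sum()
    if total > 0:
        P /= total
    return GLCMMatrix(P=P, N=levels, offsets=tuple((distance, a) for a in angles), symmetric=symmetric)


def texture_metrics(G: GLCMMatrix) -> TextureMetrics:
    """The eight texture metrics of a normalized co-occurrence matrix.

    When a marginal standard deviation is zero the correlation is undefined;
    it is reported as 0 with the ``degenerate`` flag set.
    """
    P = G.P
    N = G.N
    i = np.arange(N)[:, None]
    j = np.arange(N)[None, :]
    absdiff = np.abs(i - j)

    mean = float(np.sum(i * P))
    var = float(np.sum((i - mean) ** 2 * P))
    hom = float(np.sum(P / (1.0 + absdiff)))
    con = float(np.sum(absdiff**2 * P))
    dis = float(np.sum(absdiff * P))
    logp = np.zeros_like(P)
    np.log2(P, out=logp, where=P > 0)
    ent = float(-np.sum(P * logp))
    ene = float(np.sum(P**2))

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    x_mean = float(np.sum(np.arange(N) * px))
    y_mean = float(np.sum(np.arange(N) * py))
    sigma_x = float(np.sqrt(np.sum((np.arange(N) - x_mean) ** 2 * px)))
    sigma_y = float(np.sqrt(np.sum((np.arange(N) - y_mean) ** 2 * py)))
    degenerate = sigma_x == 0.0 or sigma_y == 0.0
    if degenerate:
        cor = 0.0
    else:
        cor = float(np.sum((i - x_mean) * (j - y_mean) * P) / (sigma_x * sigma_y))

    return TextureMetrics(
        MEAN=mean,
        VAR=var,
        HOM=hom,
        CON=con,
        DIS=dis,
        ENT=ent,
        ENE=ene,
        COR=cor,
        mu=mean,
        x_mean=x_mean,
        y_mean=y_mean,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        degenerate=degenerate,
    )


def texture_features(
    patch: PatchSample,
    band_names: tuple[str, ...],
    texture_bands: tuple[str, ...] = ("B8",),
    levels: int = DEFAULT_LEVELS,
    distance: int = DEFAULT_DISTANCE,
) -> dict[str, float]:
    """GLCM metrics for one patch, named ``GLCM_<METRIC>_<band>``.

    Texture is computed on the NIR band (B8) by default — the band with the
    strongest vegetation signal; additional bands can be listed.
    """
    values: dict[str, float] = {}
    for band in texture_bands:
        idx = band_names.index(band)
        q = quantize(patch.window[:, :, idx], levels=levels)
        metrics = texture_metrics(glcm(q, distance=distance, levels=levels))
        for name, value in metrics.as_dict().items():
            values[f"GLCM_{name}_{band}"] = value
    return values
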