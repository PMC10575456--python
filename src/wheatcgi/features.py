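"""Spectral and textural features per quadrat.

Two feature families feed the growth-index inversion models:

* Twelve vegetation indices (VIs) computed from the per-band mean
  reflectances (B, G, R, RE, NIR) of each quadrat window.
* Eight gray-level co-occurrence matrix (GLCM) texture features — mean,
  variance, contrast, dissimilarity, homogeneity, entropy, second moment
  (angular second moment / energy) and correlation — computed on the red and
  green bands of each window after 8-bit quantization.

The co-occurrence counting itself is delegated to
:func:`skimage.feature.graycomatrix`; the Haralick-style statistics are
evaluated here directly from the normalized, direction-averaged matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .imagery import BandMeans, QuadratPatch

#: The vegetation indices computed by :func:`compute_vis`, in output order.
VI_NAMES: tuple[str, ...] = (
    "RDVI", "RVI", "NDVI", "DVI", "SAVI", "OSAVI",
    "TVI", "EXR", "NDRE", "NPCI", "EVI2", "MVI",
)

#: The texture statistics computed by :func:`texture_features`, in output order.
TEXTURE_NAMES: tuple[str, ...] = (
    "mean", "var", "con", "dis", "hom", "ent", "sm", "corr",
)

#: Bands on which textures are extracted (selected for winter wheat canopies).
TEXTURE_BANDS: tuple[str, ...] = ("red", "green")

#: Column names of the 16 texture features in a feature table.
TEXTURE_COLUMNS: tuple[str, ...] = tuple(
    f"{band}_{feat}" for band in TEXTURE_BANDS for feat in TEXTURE_NAMES
)


def compute_vis(bm: BandMeans) -> dict[str, float]:
    """Evaluate the twelve vegetation indices from band-mean reflectance.

    Index formulas (reflectances B, G, R, RE, NIR)::

        RDVI  = (NIR - R) / sqrt(NIR + R)
        RVI   = NIR / R
        NDVI  = (NIR - R) / (NIR + R)
        DVI   = NIR - R
        SAVI  = 1.5 (NIR - R) / (NIR + R + 0.5)
        OSAVI = 1.16 (NIR - R) / (NIR + R + 0.16)
        TVI   = 60 (NIR - G) - 100 (R - G)
        EXR   = 1.4 R - G
        NDRE  = (NIR - RE) / (NIR + RE)
        NPCI  = (R - B) / (R + B)
        EVI2  = (NIR - R) / (1 + NIR + 2.4 R)
        MVI   = (NIR - R) / sqrt(NIR + R + 0.5)

    A vanishing denominator yields ``nan`` for that index rather than an
    exception, so a single degenerate quadrat cannot abort a batch.

    Returns
    -------
    dict
        ``{"quadrat_id": ..., "RDVI": ..., ..., "MVI": ...}``.
    """
    b, g, r = bm.blue, bm.green, bm.red
    re, nir = bm.red_edge, bm.nir

    def safe(num: float, den: float) -> float:
        return num / den if den != 0 else math.nan

    def safe_sqrt(num: float, den: float) -> float:
        return num / math.sqrt(den) if den > 0 else math.nan

    vis = {
        "RDVI": safe_sqrt(nir - r, nir + r),
        "RVI": safe(nir, r),
        "NDVI": safe(nir - r, nir + r),
        "DVI": nir - r,
        "SAVI": safe(1.5 * (nir - r), nir + r + 0.5),
        "OSAVI": safe(1.16 * (nir - r), nir + r + 0.16),
        "TVI": 60.0 * (nir - g) - 100.0 * (r - g),
        "EXR": 1.4 * r - g,
        "NDRE": safe(nir - re, nir + re),
        "NPCI": safe(r - b, r + b),
        "EVI2": safe(nir - r, 1.0 + nir + 2.4 * r),
        "MVI": safe_sqrt(nir - r, nir + r + 0.5),
    }
    return {"quadrat_id": bm.quadrat_id, **vis}


@dataclass
class GLCMSpec:
    """Configuration of the gray-level co-occurrence computation.

    Attributes
    ----------
    levels : int
        Number of gray levels N after re-quantization (default 32).
    angles_deg : tuple of float
        Co-occurrence directions; the four unit directions by default.
    distance : int
        Pixel displacement along each direction.
    symmetric : bool
        Count each pair in both orders (adds the transpose).
    source_bit_depth : int
        Bit depth of the intermediate quantization of reflectance (8).
    """

    levels: int = 32
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    distance: int = 1
    symmetric: bool = True
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.angles_deg:
            raise ValueError("at least one angle is required")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not 1 <= self.source_bit_depth <= 16:
            raise ValueError("source_bit_depth must be in [1, 16]")
        if self.levels > 2 ** self.source_bit_depth:
            raise ValueError("levels cannot exceed the source bit depth range")


def quantize(band: np.ndarray, spec: GLCMSpec | None = None) -> np.ndarray:
    """Map a real-valued band onto integer gray levels ``{0 .. N-1}``.

    The band's min–max range is first rescaled linearly onto the source bit
    depth (8-bit by default) and then reduced to ``spec.levels`` codes.  A
    constant band maps to all zeros.
    """
    spec = spec or GLCMSpec()
    band = np.asarray(band, dtype=float)
    if not np.all(np.isfinite(band)):
        raise ValueError("band contains non-finite values")
    lo, hi = band.min(), band.max()
    if hi == lo:
        return np.zeros(band.shape, dtype=np.uint8)
    full = 2 ** spec.source_bit_depth
    codes = np.floor((band - lo) / (hi - lo) * (full - 1) + 0.5).astype(np.int64)
    codes = codes * spec.levels // full
    # the top of the range belongs to the last level
    codes[codes == spec.levels] = spec.levels - 1
    return codes.astype(np.uint8)


def glcm(codes: np.ndarray, spec: GLCMSpec | None = None) -> np.ndarray:
    """Normalized co-occurrence matrix, averaged over directions.

    Pairs of gray codes at the configured displacement are counted per
    direction (optionally in both orders when symmetric), each direction's
    matrix is normalized to unit mass, and the matrices are averaged, so the
    result always satisfies ``P.sum() == 1``.
    """
    spec = spec or GLCMSpec()
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise ValueError("codes must be a 2-D array")
    if codes.min() < 0 or codes.max() >= spec.levels:
        raise ValueError(f"codes must lie in [0, {spec.levels - 1}]")
    if min(codes.shape) <= spec.distance:
        raise ValueError(
            f"patch of shape {codes.shape} too small for displacement {spec.distance}"
        )
    angles = [math.radians(a) for a in spec.angles_deg]
    mats = graycomatrix(
        codes.astype(np.uint8),
        distances=[spec.distance],
        angles=angles,
        levels=spec.levels,
        symmetric=spec.symmetric,
        normed=False,
    ).astype(float)  # (levels, levels, 1, n_angles)
    per_angle = mats[:, :, 0, :]
    totals = per_angle.sum(axis=(0, 1))
    if np.any(totals == 0):
        raise ValueError("a direction produced no pixel pairs")
    p = (per_angle / totals).mean(axis=2)
    return p


def texture_features(p: np.ndarray) -> dict[str, float]:
    """The eight Haralick-style statistics of a normalized GLCM.

    With ``i`` the row index, ``j`` the column index and ``P_ij`` the matrix
    entries (``sum P = 1``)::

        mean = sum i P_ij                 var  = sum P_ij (i - mean)^2
        con  = sum P_ij (i - j)^2         dis  = sum P_ij |i - j|
        hom  = sum P_ij / (1 + (i-j)^2)   ent  = -sum P_ij ln P_ij
        sm   = sum P_ij^2
        corr = sum P_ij (i - mu_i)(j - mu_j) / (sigma_i sigma_j)

    ``0 ln 0`` is taken as 0 and ``corr`` is defined as 0 when either
    marginal standard deviation vanishes (a constant image).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("P must be a square matrix")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("P must be normalized to unit mass")
    n = p.shape[0]
    i = np.arange(n)[:, None] * np.ones((1, n))
    j = np.ones((n, 1)) * np.arange(n)[None, :]

    mean = float((i * p).sum())
    var = float((p * (i - mean) ** 2).sum())
    con = float((p * (i - j) ** 2).sum())
    dis = float((p * np.abs(i - j)).sum())
    hom = float((p / (1.0 + (i - j) ** 2)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    ent = float(-(p * logp).sum())
    sm = float((p ** 2).sum())

    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    sd_i = math.sqrt(float((p * (i - mu_i) ** 2).sum()))
    sd_j = math.sqrt(float((p * (j - mu_j) ** 2).sum()))
    if sd_i == 0 or sd_j == 0:
        corr = 0.0
    else:
        corr = float((p * (i - mu_i) * (j - mu_j)).sum() / (sd_i * sd_j))

    return {
        "mean": mean, "var": var, "con": con, "dis": dis,
        "hom": hom, "ent": ent, "sm": sm, "corr": corr,
    }


def patch_textures(
    patch: QuadratPatch, spec: GLCMSpec | None = None
) -> list[dict[str, float]]:
    """Texture records for the red and green bands of one quadrat window.

    Each band is quantized, its co-occurrence matrix formed and the eight
    statistics evaluated, yielding two records (16 values) per quadrat.
    """
    spec = spec or GLCMSpec()
    if patch.value_kind != "reflectance":
        raise ValueError(f"quadrat {patch.quadrat_id}: expected a reflectance patch")
    records = []
    for band in TEXTURE_BANDS:
        codes = quantize(patch.band(band), spec)
        feats = texture_features(glcm(codes, spec))
        records.append({"quadrat_id": patch.quadrat_id, "band": band, **feats})
    return records


def feature_table(
    patches: list[QuadratPatch], spec: GLCMSpec | None = None
) -> pd.DataFrame:
    """Per-quadrat feature table: 5 band means, 12 VIs, 16 texture values.

    Texture columns are named ``<band>_<feature>`` (e.g. ``red_con``,
    ``green_ent``).  Row order follows the input patch order.
    """
    from .imagery import band_means  # local import to avoid cycle at module load

    spec = spec or GLCMSpec()
    rows = []
    for patch in patches:
        bm = band_means(patch)
        row: dict[str, float] = bm.as_dict()
        row.update(compute_vis(bm))
        for rec in patch_textures(patch, spec):
            band = rec["band"]
            row.update({f"{band}_{k}": rec[k] for k in TEXTURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
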