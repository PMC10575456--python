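"""Radiometric calibration and region-of-interest handling for quadrat imagery.

A UAV multispectral survey yields raw digital numbers (DN) per band.  A
calibration panel of known diffuse reflectance imaged during the flight
anchors a single-point empirical line through the origin, converting DN to
surface reflectance band by band.  Each ground quadrat is then represented by
a small square window (default 18 x 18 pixels, matching a 1 m x 1 m quadrat
at ~5.7 cm resolution) cut from the orthomosaic and summarised by its
per-band mean reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: Fixed band order used throughout the package.
BANDS: tuple[str, ...] = ("blue", "green", "red", "red_edge", "nir")

#: Sensor center wavelengths (nm), kept as metadata only.
CENTER_WAVELENGTHS_NM: dict[str, int] = {
    "blue": 450,
    "green": 560,
    "red": 650,
    "red_edge": 730,
    "nir": 840,
}


@dataclass
class QuadratPatch:
    """One quadrat's square multi-band image window.

    Parameters
    ----------
    quadrat_id : str
        Identifier of the ground quadrat the window is centered on.
    array : ndarray of shape (size, size, 5)
        Pixel values, either raw digital numbers or reflectance.
    value_kind : {"dn", "reflectance"}
        What the array holds.  Reflectance arrays are bounded to [0, 1].
    bands : tuple of str
        Band labels in array order; fixed to blue/green/red/red_edge/nir.
    """

    quadrat_id: str
    array: np.ndarray
    value_kind: str = "reflectance"
    bands: tuple[str, ...] = BANDS

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3 or self.array.shape[0] != self.array.shape[1]:
            raise ValueError(
                f"quadrat {self.quadrat_id}: patch must be square (size, size, bands), "
                f"got shape {self.array.shape}"
            )
        if self.array.shape[2] != len(self.bands):
            raise ValueError(
                f"quadrat {self.quadrat_id}: expected {len(self.bands)} bands, "
                f"got {self.array.shape[2]}"
            )
        if self.value_kind not in ("dn", "reflectance"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "reflectance":
            arr = self.array
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
                raise ValueError(
                    f"quadrat {self.quadrat_id}: reflectance values outside [0, 1]"
                )

    @property
    def size(self) -> int:
        return self.array.shape[0]

    def band(self, name: str) -> np.ndarray:
        """Return the 2-D image of one band."""
        return self.array[:, :, self.bands.index(name)]


@dataclass
class BandMeans:
    """Mean reflectance of each band over one quadrat window."""

    quadrat_id: str
    blue: float
    green: float
    red: float
    red_edge: float
    nir: float

    def as_array(self) -> np.ndarray:
        return np.array([self.blue, self.green, self.red, self.red_edge, self.nir])

    def as_dict(self) -> dict[str, float]:
        return {
            "quadrat_id": self.quadrat_id,
            "blue": self.blue,
            "green": self.green,
            "red": self.red,
            "red_edge": self.red_edge,
            "nir": self.nir,
        }


def calibrate(
    dn_patch: QuadratPatch,
    panel_dn_mean: float | np.ndarray,
    panel_reflectance: float = 0.99,
) -> QuadratPatch:
    """Convert a raw-DN patch to reflectance using a calibration panel.

    Single-point empirical line through the origin, applied per pixel and
    band::

        reflectance = DN / panel_dn_mean * panel_reflectance

    then clipped to [0, 1].  ``panel_dn_mean`` may be a scalar or one mean DN
    per band (length 5).

    Parameters
    ----------
    dn_patch : QuadratPatch
        Patch with ``value_kind == "dn"``.
    panel_dn_mean : float or array-like
        Mean digital number of the reflectance panel, per band or global.
    panel_reflectance : float
        Known diffuse reflectance of the panel (0.99 for a white standard).

    Returns
    -------
    QuadratPatch
        Reflectance patch with the same id and band order.
    """
    if dn_patch.value_kind != "dn":
        raise ValueError(f"quadrat {dn_patch.quadrat_id}: expected a DN patch")
    panel = np.asarray(panel_dn_mean, dtype=float)
    if np.any(panel <= 0):
        raise ValueError("panel_dn_mean must be positive")
    if not 0 < panel_reflectance <= 1:
        raise ValueError("panel_reflectance must be in (0, 1]")
    if panel.ndim == 1 and panel.shape[0] != len(dn_patch.bands):
        raise ValueError(
            f"per-band panel_dn_mean needs {len(dn_patch.bands)} values, "
            f"got {panel.shape[0]}"
        )
    refl = dn_patch.array.astype(float) / panel * panel_reflectance
    refl = np.clip(refl, 0.0, 1.0)
    return replace(dn_patch, array=refl, value_kind="reflectance")


def extract_roi(
    scene: np.ndarray,
    center: tuple[int, int],
    size: int,
    quadrat_id: str = "roi",
    value_kind: str = "reflectance",
) -> QuadratPatch:
    """Cut a ``size`` x ``size`` window centered on a pixel from a scene.

    The window spans rows ``[r - size//2, r - size//2 + size)`` and likewise
    for columns (0-based, half-open); for an even window the center pixel sits
    just below/right of the geometric center.

    Parameters
    ----------
    scene : ndarray of shape (H, W, 5)
        Multi-band raster.
    center : (row, col)
        Pixel coordinates of the quadrat center.
    size : int
        Window side length in pixels (the survey convention is 18).

    Raises
    ------
    ValueError
        If the window does not fit inside the scene.
    """
    scene = np.asarray(scene)
    if scene.ndim != 3:
        raise ValueError("scene must be (rows, cols, bands)")
    if size < 1:
        raise ValueError("size must be >= 1")
    r, c = int(center[0]), int(center[1])
    r0, c0 = r - size // 2, c - size // 2
    r1, c1 = r0 + size, c0 + size
    if r0 < 0 or c0 < 0 or r1 > scene.shape[0] or c1 > scene.shape[1]:
        raise ValueError(
            f"quadrat {quadrat_id}: window rows [{r0}, {r1}) cols [{c0}, {c1}) "
            f"falls outside scene of shape {scene.shape[:2]}"
        )
    return QuadratPatch(
        quadrat_id=quadrat_id,
        array=scene[r0:r1, c0:c1, :].copy(),
        value_kind=value_kind,
    )


def band_means(patch: QuadratPatch) -> BandMeans:
    """Arithmetic mean reflectance of each band over the window."""
    if patch.value_kind != "reflectance":
        raise ValueError(f"quadrat {patch.quadrat_id}: expected a reflectance patch")
    if patch.array.size == 0:
        raise ValueError(f"quadrat {patch.quadrat_id}: empty patch")
    means = patch.array.mean(axis=(0, 1))
    return BandMeans(patch.quadrat_id, *(float(v) for v in means))


def write_patch(path, patch: QuadratPatch) -> None:
    """Write a patch as a multi-band TIFF (pixel-interleaved)."""
    tifffile.imwrite(path, patch.array)


def read_patch(path, quadrat_id: str, value_kind: str = "reflectance") -> QuadratPatch:
    """Read a multi-band TIFF written by :func:`write_patch`."""
    return QuadratPatch(quadrat_id, tifffile.imread(path), value_kind=value_kind)


def read_scene(path) -> np.ndarray:
    """Read a multi-band TIFF scene as an (H, W, bands) array."""
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == len(BANDS) and arr.shape[2] != len(BANDS):
        arr = np.moveaxis(arr, 0, -1)  # band-interleaved file
    return arr
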