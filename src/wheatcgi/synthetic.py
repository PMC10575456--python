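"""Synthetic winter-wheat field generator.

No field data accompany the study design this package implements, so this
module fabricates a campaign with the same statistical skeleton: a set of
ground quadrats (default 54) whose hidden growth level varies smoothly
across the field, driving

* the ground indicators — above-ground biomass (AGB) most strongly, SPAD
  chlorophyll readings moderately and leaf water content (LWC) weakly, so a
  correlation analysis recovers the AGB > SPAD > LWC ordering;
* the canopy reflectance — red absorption deepens and near-infrared
  reflectance rises with growth, making NDVI-like indices informative;
* the spatial grain of each image patch — the correlation length of the
  within-patch reflectance field grows with canopy closure, so gray-level
  co-occurrence textures also carry growth signal.

Each quadrat yields an 18 x 18 x 5 reflectance patch and a raw digital-number
(DN) twin produced through the inverse of the calibration-panel relation, so
the full pipeline (calibration included) can run end to end offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imagery import BANDS, QuadratPatch, write_patch

#: Saturating response of each band's mean reflectance to latent growth g,
#: (bare-soil value, closed-canopy value, extinction rate k):
#:
#:     reflectance(g) = soil + (veg - soil) * (1 - exp(-k g)) / (1 - exp(-k))
#:
#: a Beer–Lambert-style canopy mixing curve.  Red absorption saturates
#: quickly with canopy closure (large k) while NIR keeps rising (small k),
#: so red-based vegetation indices flatten at high growth — the saturation
#: that motivates adding texture features in the first place.
BAND_RESPONSE: dict[str, tuple[float, float, float]] = {
    "blue": (0.08, 0.05, 5.0),
    "green": (0.10, 0.14, 4.0),
    "red": (0.30, 0.07, 6.0),
    "red_edge": (0.18, 0.30, 3.0),
    "nir": (0.25, 0.60, 2.0),
}


def _band_mean(band: str, g: float) -> float:
    soil, veg, k = BAND_RESPONSE[band]
    return soil + (veg - soil) * (1.0 - np.exp(-k * g)) / (1.0 - np.exp(-k))

#: Linear response of ground indicators to latent growth: value =
#: intercept + slope * g + noise.  Slopes are arbitrary but fixed; what
#: matters downstream is monotonicity and the relative noise levels.
GROUND_RESPONSE: dict[str, tuple[float, float]] = {
    "AGB": (50.0, 400.0),   # g dry mass per quadrat
    "SPAD": (25.0, 30.0),   # unitless meter reading
    "LWC": (0.55, 0.25),    # fraction
}

#: Relative amplitude of the spatial texture field around the band mean.
#: Canopy shadow and row structure modulate radiance strongly, so the
#: within-patch contrast is a sizeable fraction of the mean in every band.
TEXTURE_AMPLITUDE = 0.25


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic campaign.

    Defaults mirror the emulated survey: 54 quadrats, 18-pixel windows, five
    bands, a 99%-reflectance calibration panel and 16-bit DNs.  Ground noise
    standard deviations are per indicator, scaled so AGB is the cleanest
    signal and LWC the noisiest relative to its dynamic range.
    """

    n_quadrats: int = 54
    patch_size: int = 18
    bands: tuple[str, ...] = BANDS
    latent_spatial_trend: float = 0.8
    noise_sd_reflectance: float = 0.03
    noise_sd_ground: dict[str, float] = field(
        default_factory=lambda: {"AGB": 9.0, "SPAD": 1.2, "LWC": 0.015}
    )
    texture_smoothing_range: tuple[float, float] = (0.4, 1.8)
    panel_reflectance: float = 0.99
    panel_dn: int = 50000
    dn_bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_quadrats < 3:
            raise ValueError("n_quadrats must be >= 3")
        if self.patch_size < 3:
            raise ValueError("patch_size must be >= 3")
        if not 0 <= self.latent_spatial_trend <= 1:
            raise ValueError("latent_spatial_trend must be in [0, 1]")
        if self.noise_sd_reflectance < 0:
            raise ValueError("noise_sd_reflectance must be >= 0")
        if any(v < 0 for v in self.noise_sd_ground.values()):
            raise ValueError("ground noise sds must be >= 0")
        if not 0 < self.panel_reflectance <= 1:
            raise ValueError("panel_reflectance must be in (0, 1]")
        if self.panel_dn <= 0:
            raise ValueError("panel_dn must be positive")
        if self.texture_smoothing_range[0] <= 0:
            raise ValueError("texture smoothing lengths must be positive")


@dataclass
class GroundRecord:
    """Ground measurements of one quadrat."""

    quadrat_id: str
    AGB: float
    SPAD: float
    FW: float
    DW: float
    LWC: float

    def __post_init__(self) -> None:
        if not self.FW > self.DW > 0:
            raise ValueError(
                f"quadrat {self.quadrat_id}: need FW > DW > 0, got FW={self.FW}, DW={self.DW}"
            )
        if self.AGB <= 0:
            raise ValueError(f"quadrat {self.quadrat_id}: AGB must be positive")
        if not 0 <= self.SPAD <= 80:
            raise ValueError(f"quadrat {self.quadrat_id}: SPAD outside [0, 80]")


@dataclass
class SyntheticDataset:
    """One simulated campaign: reflectance and DN patches, ground table and
    the hidden growth truth (for recovery tests only — never an input)."""

    patches: list[QuadratPatch]
    dn_patches: list[QuadratPatch]
    ground: pd.DataFrame
    latent_growth: np.ndarray
    centers: pd.DataFrame
    config: SimConfig


def compute_lwc(fw: float, dw: float, quadrat_id: str = "?") -> float:
    """Leaf water content ``(FW - DW) / FW`` from fresh and dry leaf weight.

    Raises
    ------
    ValueError
        If FW is not positive or DW exceeds FW (names the quadrat).
    """
    if fw <= 0:
        raise ValueError(f"quadrat {quadrat_id}: fresh weight must be positive")
    if dw <= 0 or dw > fw:
        raise ValueError(
            f"quadrat {quadrat_id}: need 0 < DW <= FW, got FW={fw}, DW={dw}"
        )
    return (fw - dw) / fw


def _latent_growth(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Planar gradient across a quadrat grid plus uniform jitter, clipped."""
    ncols = int(np.ceil(np.sqrt(cfg.n_quadrats)))
    nrows = int(np.ceil(cfg.n_quadrats / ncols))
    idx = np.arange(cfg.n_quadrats)
    gy, gx = idx // ncols, idx % ncols
    denom = max((nrows - 1) + (ncols - 1), 1)
    t = (gy + gx) / denom  # diagonal coordinate in [0, 1]
    g = 0.5 + cfg.latent_spatial_trend * (t - 0.5)
    g = g + rng.uniform(-0.1, 0.1, size=cfg.n_quadrats)
    g = np.clip(g, 0.0, 1.0)
    spacing = cfg.patch_size + 2  # scene pixel spacing between quadrat centers
    centers = pd.DataFrame(
        {
            "quadrat_id": [f"q{i + 1:02d}" for i in idx],
            "row": gy * spacing + cfg.patch_size // 2,
            "col": gx * spacing + cfg.patch_size // 2,
        }
    )
    return g, centers


def _ground_table(
    cfg: SimConfig, g: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    records = []
    for i, gi in enumerate(g):
        qid = f"q{i + 1:02d}"
        a0, a1 = GROUND_RESPONSE["AGB"]
        s0, s1 = GROUND_RESPONSE["SPAD"]
        l0, l1 = GROUND_RESPONSE["LWC"]
        agb = max(a0 + a1 * gi + rng.normal(0, cfg.noise_sd_ground["AGB"]), 1.0)
        spad = float(np.clip(s0 + s1 * gi + rng.normal(0, cfg.noise_sd_ground["SPAD"]), 0.0, 80.0))
        lwc = float(np.clip(l0 + l1 * gi + rng.normal(0, cfg.noise_sd_ground["LWC"]), 0.05, 0.95))
        # dry leaf mass grows with the stand; FW is back-solved so that
        # LWC = (FW - DW)/FW holds exactly
        dw = 2.0 + 3.0 * gi
        fw = dw / (1.0 - lwc)
        records.append(
            GroundRecord(qid, AGB=agb, SPAD=spad, FW=fw, DW=dw,
                         LWC=compute_lwc(fw, dw, qid))
        )
    return pd.DataFrame([r.__dict__ for r in records])


def _patch_pair(
    cfg: SimConfig, gi: float, qid: str, rng: np.random.Generator
) -> tuple[QuadratPatch, QuadratPatch]:
    """One quadrat's reflectance patch and its raw-DN twin."""
    n = cfg.patch_size
    s0, s1 = cfg.texture_smoothing_range
    sigma = s0 + (s1 - s0) * gi  # canopy closure coarsens the spatial grain
    fld = gaussian_filter(rng.standard_normal((n, n)), sigma, mode="reflect")
    sd = fld.std()
    if sd > 0:
        fld = (fld - fld.mean()) / sd
    refl = np.empty((n, n, len(cfg.bands)))
    for k, band in enumerate(cfg.bands):
        mean_b = _band_mean(band, gi)
        if cfg.noise_sd_reflectance > 0:
            # quadrat-level spectral variability (soil background, stand
            # heterogeneity) that band averaging cannot remove ...
            mean_b = mean_b + rng.normal(0, cfg.noise_sd_reflectance)
        mean_b = max(mean_b, 0.01)
        layer = mean_b * (1.0 + TEXTURE_AMPLITUDE * fld)
        if cfg.noise_sd_reflectance > 0:
            # ... plus smaller per-pixel sensor noise that mostly averages out
            layer = layer + rng.normal(0, cfg.noise_sd_reflectance / 3.0, size=(n, n))
        refl[:, :, k] = np.clip(layer, 1e-4, 1.0)
    dn_max = 2 ** cfg.dn_bit_depth - 1
    dn = np.clip(
        np.round(refl / cfg.panel_reflectance * cfg.panel_dn), 0, dn_max
    ).astype(np.uint16 if cfg.dn_bit_depth <= 16 else np.uint32)
    return (
        QuadratPatch(qid, refl, value_kind="reflectance", bands=cfg.bands),
        QuadratPatch(qid, dn, value_kind="dn", bands=cfg.bands),
    )


def simulate_field(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic campaign from a :class:`SimConfig`.

    The same seed yields a bit-identical dataset.  In the noise-free limit
    every ground indicator is a strictly monotone function of the latent
    growth level, and vegetation indices computed from the patches track it
    almost perfectly.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    g, centers = _latent_growth(cfg, rng)
    ground = _ground_table(cfg, g, rng)
    patches, dn_patches = [], []
    for i, gi in enumerate(g):
        p, d = _patch_pair(cfg, float(gi), f"q{i + 1:02d}", rng)
        patches.append(p)
        dn_patches.append(d)
    return SyntheticDataset(
        patches=patches,
        dn_patches=dn_patches,
        ground=ground,
        latent_growth=g,
        centers=centers,
        config=cfg,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write a campaign to disk: per-quadrat multi-band TIFFs (DN and
    reflectance), the ground table, quadrat centers and the latent truth.

    The latent truth lands in its own CSV and is never read by the pipeline.
    """
    outdir = Path(outdir)
    (outdir / "patches").mkdir(parents=True, exist_ok=True)
    for p, d in zip(ds.patches, ds.dn_patches):
        write_patch(outdir / "patches" / f"{p.quadrat_id}_reflectance.tif", p)
        write_patch(outdir / "patches" / f"{d.quadrat_id}_dn.tif", d)
    ds.ground[["quadrat_id", "AGB", "SPAD", "FW", "DW", "LWC"]].to_csv(
        outdir / "ground.csv", index=False
    )
    ds.centers.to_csv(outdir / "centers.csv", index=False)
    pd.DataFrame(
        {"quadrat_id": ds.ground["quadrat_id"], "latent_growth": ds.latent_growth}
    ).to_csv(outdir / "latent_truth.csv", index=False)
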