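"""Procedural trichrome-like skin renders with a known severity.

A render is a layered raster: background margin, a thin dark epidermis band,
a large dermis interior, and a pale subcutis band, with smooth per-column
wobble on the band boundaries.  Dermal fibrosis is emulated by oriented
collagen "streaks" — short, roughly horizontal line segments blended toward
the blue collagen hue of a Masson's trichrome stain — whose number grows
linearly with the latent severity.  Streak parameters are drawn sequentially
from one seeded stream, so the streaks at a lower severity are a strict
prefix of those at a higher severity under the same seed; the module's
texture statistic (the blue-excess pixel fraction inside the dermis) is
therefore strictly increasing in severity at a fixed seed.

This is deliberately not photorealistic histology: it gives the feature
pipeline a texture whose monotone link to severity is known by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..errors import ValidationError

# mask label codes
BACKGROUND = 0
EPIDERMIS = 1
DERMIS = 2
SUBCUTIS = 3

MASK_LEGEND = {
    "background": BACKGROUND,
    "epidermis": EPIDERMIS,
    "dermis": DERMIS,
    "subcutis": SUBCUTIS,
}

# trichrome-like palette (RGB, uint8 scale)
_COLOR_BACKGROUND = np.array([245.0, 243.0, 246.0])
_COLOR_EPIDERMIS = np.array([148.0, 62.0, 92.0])
_COLOR_DERMIS = np.array([208.0, 144.0, 164.0])
_COLOR_SUBCUTIS = np.array([232.0, 216.0, 226.0])
_COLOR_COLLAGEN = np.array([66.0, 88.0, 172.0])

#: streaks per mm^2 of dermis at severity 0 and severity 1
_STREAK_DENSITY_LO = 20.0
_STREAK_DENSITY_HI = 420.0

#: side of the default feature patch (mm) used for the sizing precondition
_DEFAULT_PATCH_AREA_MM2 = 0.16


@dataclass
class BiopsyImage:
    """Raster, calibration, compartment mask and (optionally) true severity."""

    pixels: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float
    mask: np.ndarray  # (H, W) uint8 over {0,1,2,3}
    severity_truth: float | None = None
    biopsy_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValidationError(
                f"pixels {self.pixels.shape[:2]} and mask {self.mask.shape} "
                "must share height/width"
            )
        if self.microns_per_pixel <= 0:
            raise ValidationError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )
        labels = np.unique(self.mask)
        if not np.all(np.isin(labels, list(MASK_LEGEND.values()))):
            raise ValidationError(f"mask contains labels outside 0..3: {labels}")


def _smooth_wobble(rng: np.random.Generator, width: int, amplitude: float) -> np.ndarray:
    """Smooth per-column offset: a sum of a few random low-frequency sinusoids."""
    x = np.linspace(0, 2 * np.pi, width)
    w = np.zeros(width)
    for _ in range(3):
        freq = rng.uniform(0.5, 2.5)
        phase = rng.uniform(0, 2 * np.pi)
        w += rng.uniform(0.3, 1.0) * np.sin(freq * x + phase)
    return amplitude * w / 3.0


def render_biopsy(
    severity: float,
    microns_per_pixel: float = 1.0,
    height_px: int = 2048,
    width_px: int = 2048,
    seed: int = 0,
    biopsy_id: str = "",
) -> BiopsyImage:
    """Render one trichrome-like section at the given latent severity."""
    if not (0.0 <= severity <= 1.0):
        raise ValidationError(f"severity must lie in [0, 1], got {severity}")
    if microns_per_pixel <= 0:
        raise ValidationError(f"microns_per_pixel must be > 0, got {microns_per_pixel}")

    patch_side_px = round(1000.0 * np.sqrt(_DEFAULT_PATCH_AREA_MM2) / microns_per_pixel)
    # the dermis occupies ~60% of the tissue rows; require room for one patch
    if height_px * 0.5 < patch_side_px or width_px * 0.9 < patch_side_px:
        raise ValidationError(
            f"image {height_px}x{width_px} px at {microns_per_pixel} um/px cannot "
            f"contain one default {patch_side_px}px patch in the dermis"
        )

    layout_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    streak_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 33]))

    h, w = height_px, width_px
    margin_side = max(2, int(0.03 * w))
    margin_top = max(2, int(0.02 * h))

    tissue_top = margin_top
    tissue_bottom = h - margin_top
    tissue_rows = tissue_bottom - tissue_top

    # epidermis ~100 um thick; layout is severity-independent so that at a
    # fixed seed the streaks at low severity are an exact prefix of those at
    # high severity (epidermal thinning is carried by the score sheets, not
    # the render)
    epi_px = max(3, int(100.0 / microns_per_pixel))
    dermis_frac = 0.62
    wobble = _smooth_wobble(layout_rng, w, 0.01 * h)

    cols = np.arange(w)
    epi_top = tissue_top + wobble
    epi_bot = epi_top + epi_px
    derm_bot = epi_bot + dermis_frac * tissue_rows + _smooth_wobble(layout_rng, w, 0.01 * h)

    rows = np.arange(h)[:, None].astype(float)
    mask = np.full((h, w), BACKGROUND, dtype=np.uint8)
    in_cols = (cols >= margin_side) & (cols < w - margin_side)
    tissue = (rows >= epi_top[None, :]) & (rows < tissue_bottom) & in_cols[None, :]
    mask[tissue] = SUBCUTIS
    mask[tissue & (rows < derm_bot[None, :])] = DERMIS
    mask[tissue & (rows < epi_bot[None, :])] = EPIDERMIS

    pixels = np.empty((h, w, 3), dtype=float)
    pixels[:] = _COLOR_BACKGROUND
    pixels[mask == EPIDERMIS] = _COLOR_EPIDERMIS
    pixels[mask == DERMIS] = _COLOR_DERMIS
    pixels[mask == SUBCUTIS] = _COLOR_SUBCUTIS

    # collagen streaks in the dermis; count linear in severity
    mm2_per_px = (microns_per_pixel / 1000.0) ** 2
    dermis_area_mm2 = float(np.sum(mask == DERMIS)) * mm2_per_px
    density = _STREAK_DENSITY_LO + (_STREAK_DENSITY_HI - _STREAK_DENSITY_LO) * severity
    n_streaks = int(round(density * dermis_area_mm2))

    derm_rows = np.where((mask == DERMIS).any(axis=1))[0]
    r_lo, r_hi = int(derm_rows.min()), int(derm_rows.max())
    for _ in range(n_streaks):
        # fixed draw count per streak => prefix property across severities
        u = streak_rng.uniform(size=6)
        cy = r_lo + u[0] * (r_hi - r_lo)
        cx = margin_side + u[1] * (w - 2 * margin_side)
        theta = (u[2] - 0.5) * np.deg2rad(50.0)
        length = (60.0 + 120.0 * u[3]) / microns_per_pixel
        thickness = 1 + int(u[4] * 2.5)
        alpha = 0.45 + 0.4 * u[5]
        t = np.arange(-length / 2, length / 2)
        rr = np.round(cy + t * np.sin(theta)).astype(int)
        cc = np.round(cx + t * np.cos(theta)).astype(int)
        for dr in range(thickness):
            r_idx = np.clip(rr + dr, 0, h - 1)
            c_idx = np.clip(cc, 0, w - 1)
            keep = mask[r_idx, c_idx] == DERMIS
            ri, ci = r_idx[keep], c_idx[keep]
            pixels[ri, ci] = (1 - alpha) * pixels[ri, ci] + alpha * _COLOR_COLLAGEN

    pixels += noise_rng.normal(0.0, 5.0, size=pixels.shape)
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)

    return BiopsyImage(
        pixels=pixels,
        microns_per_pixel=float(microns_per_pixel),
        mask=mask,
        severity_truth=float(severity),
        biopsy_id=biopsy_id,
    )


def collagen_streak_density(image: BiopsyImage) -> float:
    """Texture statistic T: fraction of dermis pixels with strong blue excess.

    Blue excess (B - (R+G)/2) picks out collagen-blended pixels against the
    pink dermis base; T grows strictly with the number of rendered streaks.
    """
    px = image.pixels.astype(float)
    excess = px[:, :, 2] - 0.5 * (px[:, :, 0] + px[:, :, 1])
    dermis = image.mask == DERMIS
    if not dermis.any():
        raise ValidationError("image has no dermis pixels")
    return float(np.mean(excess[dermis] > 25.0))


def save_biopsy(image: BiopsyImage, directory: str | Path, stem: str) -> dict[str, Path]:
    """Write pixels and mask as TIFF plus a sidecar JSON with calibration."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pixels_path = directory / f"{stem}.tif"
    mask_path = directory / f"{stem}_mask.tif"
    sidecar_path = directory / f"{stem}.json"
    tifffile.imwrite(pixels_path, image.pixels)
    tifffile.imwrite(mask_path, image.mask)
    sidecar = {
        "microns_per_pixel": image.microns_per_pixel,
        "mask_legend": MASK_LEGEND,
        "severity_truth": image.severity_truth,
        "biopsy_id": image.biopsy_id,
        "mask_path": mask_path.name,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"pixels": pixels_path, "mask": mask_path, "sidecar": sidecar_path}


def load_biopsy(pixels_path: str | Path) -> BiopsyImage:
    """Read a biopsy written by :func:`save_biopsy`."""
    import tifffile

    pixels_path = Path(pixels_path)
    sidecar_path = pixels_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar JSON {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    mask = tifffile.imread(pixels_path.parent / meta["mask_path"])
    return BiopsyImage(
        pixels=tifffile.imread(pixels_path),
        microns_per_pixel=float(meta["microns_per_pixel"]),
        mask=mask.astype(np.uint8),
        severity_truth=meta.get("severity_truth"),
        biopsy_id=meta.get("biopsy_id", ""),
    )
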