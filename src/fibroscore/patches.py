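"""Dermis-restricted patch sampling and chunked-store conversion.

Whole-slide rasters are converted losslessly into a chunked (zarr) store with
the micron-per-pixel calibration preserved as an attribute.  Feature patches
are square, with side length derived from a target area (default 0.16 mm²,
i.e. 400 px at 1 µm/px), and are drawn uniformly at random among all top-left
corners whose window contains at least ``min_dermis_fraction`` dermis pixels;
the epidermis and subcutis are thereby excluded.  Coordinates are 0-based,
row-major, with the patch origin at its top-left pixel.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConversionError, SamplingError, ValidationError
from .synthetic.imaging import DERMIS, MASK_LEGEND, BiopsyImage

logger = logging.getLogger(__name__)


@dataclass
class Patch:
    """One square patch: provenance (origin, side) plus its pixel block."""

    patch_id: int
    origin_rc: tuple[int, int]
    side_px: int
    pixels: np.ndarray
    area_mm2: float
    dermis_fraction: float = 1.0


@dataclass
class PatchSet:
    biopsy_id: str
    patches: list[Patch]
    sampling_seed: int
    n_requested: int
    microns_per_pixel: float = 1.0

    def __len__(self) -> int:
        return len(self.patches)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "biopsy_id": self.biopsy_id,
                "patch_id": p.patch_id,
                "row": p.origin_rc[0],
                "col": p.origin_rc[1],
                "side_px": p.side_px,
                "dermis_fraction": p.dermis_fraction,
                "seed": self.sampling_seed,
            }
            for p in self.patches
        ]
        return pd.DataFrame(rows)


def patch_side_px(patch_area_mm2: float, microns_per_pixel: float) -> int:
    """Side of a square patch of the target area: round(1000*sqrt(A)/mpp)."""
    return int(round(1000.0 * np.sqrt(patch_area_mm2) / microns_per_pixel))


def _window_fraction(indicator: np.ndarray, side: int) -> np.ndarray:
    """Fraction of ones in every side x side window (top-left indexed),
    via a summed-area table."""
    ii = np.zeros((indicator.shape[0] + 1, indicator.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(indicator, axis=0), axis=1, out=ii[1:, 1:])
    h, w = indicator.shape
    n_r, n_c = h - side + 1, w - side + 1
    if n_r <= 0 or n_c <= 0:
        return np.zeros((0, 0))
    sums = (
        ii[side : side + n_r, side : side + n_c]
        - ii[:n_r, side : side + n_c]
        - ii[side : side + n_r, :n_c]
        + ii[:n_r, :n_c]
    )
    return sums / float(side * side)


def sample_patches(
    image: BiopsyImage,
    n: int = 100,
    patch_area_mm2: float = 0.16,
    seed: int = 0,
    min_dermis_fraction: float = 0.9,
) -> PatchSet:
    """Uniformly sample ``n`` dermis patches of the target area.

    Positions are drawn without positional replacement among eligible
    top-left corners (window dermis fraction >= ``min_dermis_fraction``).
    When fewer than ``n`` eligible corners exist, sampling falls back to
    replacement and logs a warning.  Deterministic for a fixed seed.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if patch_area_mm2 <= 0:
        raise ValidationError(f"patch_area_mm2 must be positive, got {patch_area_mm2}")
    if not (0.0 < min_dermis_fraction <= 1.0):
        raise ValidationError(
            f"min_dermis_fraction must lie in (0, 1], got {min_dermis_fraction}"
        )
    side = patch_side_px(patch_area_mm2, image.microns_per_pixel)
    h, w = image.mask.shape
    if side > h or side > w:
        raise SamplingError(
            f"patch side {side}px exceeds image bounds {h}x{w}"
        )
    dermis = (image.mask == DERMIS).astype(np.int64)
    if dermis.sum() == 0:
        raise SamplingError("mask contains no dermis pixels")
    frac = _window_fraction(dermis, side)
    eligible = np.argwhere(frac >= min_dermis_fraction)
    if eligible.shape[0] == 0:
        raise SamplingError(
            f"no {side}px patch position reaches dermis fraction "
            f">= {min_dermis_fraction}"
        )
    rng = np.random.default_rng(seed)
    if eligible.shape[0] >= n:
        idx = rng.choice(eligible.shape[0], size=n, replace=False)
    else:
        msg = (
            f"only {eligible.shape[0]} eligible positions for {n} requested "
            "patches; sampling with replacement"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        idx = rng.choice(eligible.shape[0], size=n, replace=True)
    patches = []
    for k, i in enumerate(idx):
        r, c = (int(v) for v in eligible[i])
        patches.append(
            Patch(
                patch_id=k,
                origin_rc=(r, c),
                side_px=side,
                pixels=image.pixels[r : r + side, c : c + side].copy(),
                area_mm2=(side * image.microns_per_pixel / 1000.0) ** 2,
                dermis_fraction=float(frac[r, c]),
            )
        )
    return PatchSet(
        biopsy_id=image.biopsy_id,
        patches=patches,
        sampling_seed=int(seed),
        n_requested=int(n),
        microns_per_pixel=image.microns_per_pixel,
    )


# --------------------------------------------------------------------------
# Chunked store conversion
# --------------------------------------------------------------------------

def convert_to_store(
    image_path: str | Path,
    store_path: str | Path | None = None,
    chunks: tuple[int, int, int] = (512, 512, 3),
) -> Path:
    """Losslessly copy a slide raster into a zarr store.

    Resolution metadata is read from the sidecar JSON next to the raster
    (``<stem>.json`` with a ``microns_per_pixel`` key); without it the
    conversion refuses to guess.  A mask raster referenced by the sidecar is
    copied alongside the pixels.
    """
    import tifffile
    import zarr

    image_path = Path(image_path)
    if not image_path.exists():
        raise ConversionError(f"raster not found: {image_path}")
    sidecar_path = image_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ConversionError(
            f"no resolution metadata: provide a sidecar JSON at {sidecar_path} "
            "with a 'microns_per_pixel' key"
        )
    meta = json.loads(sidecar_path.read_text())
    if "microns_per_pixel" not in meta:
        raise ConversionError(
            f"sidecar {sidecar_path} lacks the 'microns_per_pixel' key"
        )
    if image_path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(image_path)
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(image_path))
    store_path = Path(store_path) if store_path else image_path.with_suffix(".zarr")
    group = zarr.open_group(str(store_path), mode="w")
    arr = group.create_array(
        "pixels", shape=pixels.shape, dtype=pixels.dtype,
        chunks=chunks[: pixels.ndim],
    )
    arr[:] = pixels
    group.attrs["microns_per_pixel"] = float(meta["microns_per_pixel"])
    group.attrs["mask_legend"] = {k: int(v) for k, v in MASK_LEGEND.items()}
    if meta.get("mask_path"):
        mask = tifffile.imread(image_path.parent / meta["mask_path"])
        m = group.create_array(
            "mask", shape=mask.shape, dtype=mask.dtype, chunks=chunks[:2]
        )
        m[:] = mask
    if meta.get("severity_truth") is not None:
        group.attrs["severity_truth"] = float(meta["severity_truth"])
    return store_path


def load_store(store_path: str | Path) -> BiopsyImage:
    """Reconstruct a :class:`BiopsyImage` from a converted store."""
    import zarr

    group = zarr.open_group(str(store_path), mode="r")
    if "mask" not in group:
        raise ConversionError(f"store {store_path} holds no mask array")
    return BiopsyImage(
        pixels=group["pixels"][:],
        microns_per_pixel=float(group.attrs["microns_per_pixel"]),
        mask=group["mask"][:].astype(np.uint8),
        severity_truth=group.attrs.get("severity_truth"),
        biopsy_id=str(group.attrs.get("biopsy_id", "")),
    )
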