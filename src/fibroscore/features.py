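"""Quantitative image features (QIFs): fixed-length vectors per patch.

The pipeline's contract with its feature extractor is minimal: a
deterministic map from an RGB patch to a fixed-width vector, constant across
one run.  Two backends realize it:

* :class:`TextureFeatureExtractor` — the default, dependency-free backend: a
  bank of multiscale texture statistics (channel moments, gradient
  orientation histograms, difference-of-Gaussian band-pass energies,
  collagen blue-excess summaries) expanded to the requested width by a
  fixed, seeded random linear projection.  The projection preserves the
  4,096-wide matrix geometry of a CNN fully-connected layer so every
  downstream code path is identical.
* :class:`OnnxCnnBackend` — reads activations of a named layer of a local
  ONNX model (e.g. an ImageNet-pretrained AlexNet fully-connected layer,
  4,096 wide).  The model file must be provisioned manually; the library
  never downloads anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DimensionError, ProvisioningError, ValidationError
from .patches import Patch, PatchSet


@dataclass
class QifMatrix:
    """n_patches x n_features feature block for one biopsy."""

    biopsy_id: str
    values: np.ndarray
    backend_name: str
    patch_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("QIF values must be a 2-D matrix")
        if len(self.patch_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.patch_ids)} patch ids for {self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("QIF matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])

    @property
    def n_patches(self) -> int:
        return int(self.values.shape[0])


# --------------------------------------------------------------------------
# Texture backend
# --------------------------------------------------------------------------

_BANDPASS_SIGMAS = ((1, 2), (2, 4), (4, 8), (8, 16))
_N_ORIENT_BINS = 8


def _base_feature_names() -> list[str]:
    names = []
    for ch in "rgb":
        names += [f"mean_{ch}", f"std_{ch}", f"mad_{ch}"]
    names += ["mean_blue_excess", "std_blue_excess", "frac_blue_excess"]
    names += ["grad_mag_mean", "grad_mag_std"]
    names += [f"orient_hist_{k}" for k in range(_N_ORIENT_BINS)]
    for lo, hi in _BANDPASS_SIGMAS:
        names.append(f"bandpass_gray_{lo}_{hi}")
    for lo, hi in _BANDPASS_SIGMAS:
        names.append(f"bandpass_blue_{lo}_{hi}")
    return names


BASE_FEATURE_NAMES: tuple[str, ...] = tuple(_base_feature_names())

#: base features that measure contrast/variation; exactly 0 on a constant patch
CONTRAST_FEATURE_NAMES: tuple[str, ...] = tuple(
    n for n in BASE_FEATURE_NAMES
    if n.startswith(("std_", "mad_", "grad_", "orient_", "bandpass_"))
)


def texture_base_features(pixels: np.ndarray) -> np.ndarray:
    """The deterministic base bank of multiscale texture statistics."""
    px = np.asarray(pixels, dtype=float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValidationError(f"expected an (H, W, 3) patch, got shape {px.shape}")
    px = px / 255.0
    feats: list[float] = []
    for c in range(3):
        ch = px[:, :, c]
        # anchor-shifted deviations: exact zeros on a constant field
        d = ch - ch[0, 0]
        feats += [ch.mean(), d.std(), np.abs(d - d.mean()).mean()]
    blue_excess = px[:, :, 2] - 0.5 * (px[:, :, 0] + px[:, :, 1])
    feats += [
        blue_excess.mean(),
        (blue_excess - blue_excess[0, 0]).std(),
        float(np.mean(blue_excess > 0.1)),
    ]
    gray = px.mean(axis=2)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    feats += [mag.mean(), mag.std()]
    theta = np.arctan2(gy, gx) % np.pi  # orientation, not direction
    hist, _ = np.histogram(
        theta, bins=_N_ORIENT_BINS, range=(0, np.pi), weights=mag
    )
    total = hist.sum()
    feats += list(hist / total if total > 0 else hist)
    for channel in (gray, blue_excess):
        shifted = channel - channel[0, 0]  # exact zero band on a flat field
        for lo, hi in _BANDPASS_SIGMAS:
            band = ndimage.gaussian_filter(shifted, lo) - ndimage.gaussian_filter(
                shifted, hi
            )
            feats.append(band.std())
    return np.asarray(feats, dtype=float)


class TextureFeatureExtractor(TransformerMixin, BaseEstimator):
    """Deterministic texture-statistics backend with seeded linear expansion.

    Parameters
    ----------
    n_features : int
        Output width per patch (default 4096, matching a CNN fc layer).
    random_state : int
        Seed of the fixed Gaussian projection from the base bank to the
        output width.  Two instances with equal seeds produce identical
        vectors on identical patches.
    """

    name = "texture"
    deterministic = True

    def __init__(self, n_features: int = 4096, random_state: int = 0):
        self.n_features = n_features
        self.random_state = random_state

    @property
    def config(self) -> dict:
        return {"n_features": self.n_features, "random_state": self.random_state}

    def _ensure_projection(self) -> None:
        if self.n_features < 1:
            raise ValidationError(f"n_features must be >= 1, got {self.n_features}")
        if not hasattr(self, "projection_"):
            n_base = len(BASE_FEATURE_NAMES)
            rng = np.random.default_rng(self.random_state)
            self.projection_ = rng.normal(
                0.0, 1.0 / np.sqrt(n_base), size=(n_base, self.n_features)
            )

    def fit(self, X=None, y=None):  # data-independent: fixes the projection
        self._ensure_projection()
        return self

    def features(self, pixels: np.ndarray) -> np.ndarray:
        """Feature vector for one patch raster."""
        self._ensure_projection()
        return texture_base_features(pixels) @ self.projection_

    def transform(self, X) -> np.ndarray:
        """Rows of features for a sequence of patches / patch rasters."""
        self._ensure_projection()
        items = X.patches if isinstance(X, PatchSet) else X
        rows = []
        for item in items:
            pixels = item.pixels if isinstance(item, Patch) else np.asarray(item)
            rows.append(self.features(pixels))
        return np.vstack(rows) if rows else np.empty((0, self.n_features))


def texture_backend(n_features: int = 4096, seed: int = 0) -> TextureFeatureExtractor:
    """Convenience constructor for the default backend."""
    return TextureFeatureExtractor(n_features=n_features, random_state=seed).fit()


# --------------------------------------------------------------------------
# ONNX CNN backend
# --------------------------------------------------------------------------

#: ImageNet normalization constants applied before CNN inference.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class OnnxCnnBackend:
    """Feature backend reading a named layer of a local ONNX CNN.

    ``model_path`` must point at an already-provisioned model file (for the
    AlexNet case, a fully-connected layer 4,096 wide); no download is ever
    attempted.  ``layer`` is the output name to read — it is a required
    configuration value, not a guess.
    """

    model_path: str | Path
    layer: str
    n_features: int = 4096
    input_size: int = 224
    name: str = "onnx_cnn"
    deterministic: bool = True
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.model_path = Path(self.model_path)
        if not self.model_path.exists():
            raise ProvisioningError(
                f"ONNX model file not found at {self.model_path}; provision it "
                "manually (the library performs no network access)"
            )
        try:
            import onnxruntime
        except ImportError as exc:
            raise ProvisioningError(
                "onnxruntime is not installed; install it to use the CNN backend"
            ) from exc
        self._session = onnxruntime.InferenceSession(str(self.model_path))
        self.config = {
            "model_path": str(self.model_path),
            "layer": self.layer,
            "input_size": self.input_size,
            "normalization": {"mean": IMAGENET_MEAN, "std": IMAGENET_STD},
        }

    def features(self, pixels: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        img = resize(
            np.asarray(pixels, dtype=float) / 255.0,
            (self.input_size, self.input_size),
            anti_aliasing=True,
        )
        img = (img - np.asarray(IMAGENET_MEAN)) / np.asarray(IMAGENET_STD)
        tensor = img.transpose(2, 0, 1)[None].astype(np.float32)
        input_name = self._session.get_inputs()[0].name
        (out,) = self._session.run([self.layer], {input_name: tensor})
        vec = np.asarray(out).ravel()
        if vec.size != self.n_features:
            raise DimensionError(
                f"layer '{self.layer}' emitted {vec.size} values, "
                f"expected {self.n_features}"
            )
        return vec.astype(float)


def onnx_cnn_backend(
    model_path: str | Path, layer: str, n_features: int = 4096
) -> OnnxCnnBackend:
    return OnnxCnnBackend(model_path=model_path, layer=layer, n_features=n_features)


# --------------------------------------------------------------------------
# Extraction
# --------------------------------------------------------------------------

def extract_features(patches: PatchSet, backend) -> QifMatrix:
    """One feature row per patch, in patch order."""
    if len(patches) == 0:
        raise ValidationError("patch set is empty")
    rows = []
    width = None
    for patch in patches.patches:
        try:
            vec = np.asarray(backend.features(patch.pixels), dtype=float)
        except Exception as exc:  # noqa: BLE001 - re-raise with provenance
            raise RuntimeError(
                f"backend '{getattr(backend, 'name', backend)}' failed on "
                f"patch {patch.patch_id} of biopsy '{patches.biopsy_id}'"
            ) from exc
        if not np.all(np.isfinite(vec)):
            raise ValidationError(
                f"non-finite features for patch {patch.patch_id} "
                f"of biopsy '{patches.biopsy_id}'"
            )
        if width is None:
            width = vec.size
        elif vec.size != width:
            raise DimensionError(
                f"inconsistent feature width on patch {patch.patch_id}: "
                f"{vec.size} != {width}"
            )
        rows.append(vec)
    return QifMatrix(
        biopsy_id=patches.biopsy_id,
        values=np.vstack(rows),
        backend_name=getattr(backend, "name", type(backend).__name__),
        patch_ids=[p.patch_id for p in patches.patches],
    )


def save_qif(store_path: str | Path, qif: QifMatrix) -> None:
    """Persist a QIF matrix under ``<biopsy_id>/qif`` in a zarr store."""
    import zarr

    group = zarr.open_group(str(store_path), mode="a")
    sub = group.require_group(qif.biopsy_id)
    if "qif" in sub:
        del sub["qif"]
    arr = sub.create_array("qif", shape=qif.values.shape, dtype="float64")
    arr[:] = qif.values
    arr.attrs["backend_name"] = qif.backend_name
    arr.attrs["n_features"] = qif.n_features
    arr.attrs["patch_ids"] = [int(i) for i in qif.patch_ids]


def load_qif(store_path: str | Path, biopsy_id: str) -> QifMatrix:
    import zarr

    group = zarr.open_group(str(store_path), mode="r")
    arr = group[biopsy_id]["qif"]
    return QifMatrix(
        biopsy_id=biopsy_id,
        values=arr[:],
        backend_name=str(arr.attrs["backend_name"]),
        patch_ids=list(arr.attrs["patch_ids"]),
    )
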