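"""Reading, polarity normalization and segmentation of cross-section stacks.

A specimen is imaged as 20 grayscale tomographic sections (10 horizontal,
10 vertical). Cracks appear as thin elongated regions whose intensity
differs from the surrounding solid material; depending on the rendering
convention they may be darker or brighter than the solid ("polarity").
All downstream processing assumes the cracks-dark convention, so stacks
are normalized on ingest.

Segmentation turns each section into a four-class label mask:

* background — pixels outside the object support,
* solid      — intact material,
* damage     — crack interior,
* boundary   — optional band of pixels flanking every solid/damage
               interface, giving the "point on the crack boundary" case
               a concrete raster meaning.

The object support is found by a global foreground threshold, keeping the
largest 8-connected component and filling its internal holes (a seed
section is a single solid body whose internal cracks must not be counted
as background). Cracks are then split from solid by a second threshold
computed within the support (Otsu by default, or a fixed intensity), and
speckles below a minimum area are returned to solid.

Coordinate convention, used package-wide: pixel (row, col), 0-based,
row-major; x is the column index, y the row index; a real-valued point
(x, y) lies in the pixel (floor(y), floor(x)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (FormatError, ManifestError, ParameterError,
                     SegmentationError)
from .labels import BACKGROUND, BOUNDARY, DAMAGE, SOLID

CRACKS_DARK = "cracks-dark"
CRACKS_BRIGHT = "cracks-bright"

_SUPPORTED_DTYPES = (np.uint8, np.uint16)


@dataclass(frozen=True)
class GrayscaleSlice:
    """One tomographic cross-section plus its acquisition metadata."""

    pixels: np.ndarray
    slice_index: int
    orientation: str = "horizontal"  # or "vertical"
    pixel_pitch: float = 0.05        # mm per pixel
    polarity: str = CRACKS_DARK

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise FormatError("slice raster must be a non-empty 2D array")
        if px.dtype not in _SUPPORTED_DTYPES:
            raise FormatError(
                f"unsupported bit depth {px.dtype}; expected uint8 or uint16")
        if self.polarity not in (CRACKS_DARK, CRACKS_BRIGHT):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def intensity_max(self) -> int:
        return int(np.iinfo(self.pixels.dtype).max)


def normalize_polarity(slc: GrayscaleSlice) -> GrayscaleSlice:
    """Return the slice in the cracks-dark convention.

    Cracks-bright slices are intensity-inverted (v -> max - v); slices
    already cracks-dark are returned unchanged, so the operation is
    idempotent on its output.
    """
    if slc.polarity == CRACKS_DARK:
        return slc
    inverted = (np.iinfo(slc.pixels.dtype).max - slc.pixels).astype(slc.pixels.dtype)
    return replace(slc, pixels=inverted, polarity=CRACKS_DARK)


# ---------------------------------------------------------------------------
# manifest I/O

def read_stack(manifest_path) -> list[GrayscaleSlice]:
    """Read a slice stack described by a JSON manifest.

    The manifest (written by the phantom generator, or hand-authored for
    real data) lists, per slice, the image file, slice_index and
    orientation, plus stack-level pixel_pitch and polarity. Slices are
    returned ordered by slice_index; pixel data are loaded losslessly.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        try:
            manifest = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ManifestError(f"malformed manifest {manifest_path}: {exc}") from exc

    entries = manifest.get("slices")
    if not entries:
        raise ManifestError(f"manifest {manifest_path} lists no slices")
    pitch = float(manifest.get("pixel_pitch", 0.05))
    polarity = manifest.get("polarity", CRACKS_DARK)

    seen = set()
    slices = []
    root = manifest_path.parent
    for entry in entries:
        idx = int(entry["slice_index"])
        if idx in seen:
            raise ManifestError(f"duplicate slice_index {idx} in {manifest_path}")
        seen.add(idx)
        img_path = root / entry["file"]
        if not img_path.exists():
            raise FileNotFoundError(f"slice image not found: {img_path}")
        px = _read_gray(img_path)
        slices.append(GrayscaleSlice(
            pixels=px, slice_index=idx,
            orientation=entry.get("orientation", "horizontal"),
            pixel_pitch=pitch, polarity=entry.get("polarity", polarity)))
    slices.sort(key=lambda s: s.slice_index)
    return slices


def _read_gray(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[-1] == 1:
        px = px[..., 0]
    if px.ndim != 2:
        raise FormatError(f"{path}: expected single-channel grayscale image")
    if px.dtype not in _SUPPORTED_DTYPES:
        raise FormatError(f"{path}: unsupported bit depth {px.dtype}")
    return px


def read_masks(manifest_path) -> list[np.ndarray]:
    """Read the label masks referenced by a manifest (phantom stacks only)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    masks = []
    for entry in sorted(manifest["slices"], key=lambda e: e["slice_index"]):
        if "mask" not in entry:
            raise ManifestError(f"manifest entry {entry['slice_index']} has no mask")
        masks.append(_read_gray(root / entry["mask"]).astype(np.uint8))
    return masks


# ---------------------------------------------------------------------------
# segmentation

@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for the threshold-based crack segmenter.

    background_threshold
        Intensity separating background from the object; None computes a
        global Otsu split of the whole slice.
    crack_threshold
        Intensity at or below which an in-object pixel is crack; None
        computes an Otsu split within the object support.
    min_speckle_px
        Connected damage components smaller than this (8-connectivity)
        are reassigned to solid; 0 disables the filter.
    boundary_band_px
        Half-width of the boundary band grown around every solid/damage
        interface; 0 disables the boundary class.
    min_contrast
        Minimum solid-vs-crack mean-intensity separation for an automatic
        (Otsu) crack threshold to be trusted; guards against splitting
        pure noise in crack-free sections. Ignored for fixed thresholds.
    """

    background_threshold: Optional[float] = None
    crack_threshold: Optional[float] = None
    min_speckle_px: int = 5
    boundary_band_px: int = 0
    min_contrast: float = 20.0

    def validate(self, intensity_max: int) -> None:
        for name in ("background_threshold", "crack_threshold"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= intensity_max):
                raise ParameterError(
                    f"{name}={v} outside intensity range [0, {intensity_max}]")
        if self.min_speckle_px < 0 or self.boundary_band_px < 0:
            raise ParameterError("pixel counts must be non-negative")


def segment_slice(slc: GrayscaleSlice,
                  config: SegmentationConfig | None = None) -> np.ndarray:
    """Segment one cross-section into a background/solid/damage(/boundary) mask.

    The slice is polarity-normalized first, so either convention is
    accepted. Returns a uint8 label mask of the slice's shape.
    """
    config = config or SegmentationConfig()
    slc = normalize_polarity(slc)
    config.validate(slc.intensity_max)
    img = slc.pixels.astype(np.float64)

    bg_t = config.background_threshold
    if bg_t is None:
        if np.ptp(img) == 0:
            raise SegmentationError("slice has constant intensity; no object found")
        bg_t = threshold_otsu(img)
    fg = img > bg_t
    if not fg.any():
        raise SegmentationError("no foreground above the background threshold")

    # single solid body: largest 8-connected component, holes (cracks) filled
    comps = cc_label(fg, connectivity=2)
    largest = np.argmax(np.bincount(comps.ravel())[1:]) + 1
    support = ndimage.binary_fill_holes(comps == largest)

    damage = _crack_pixels(img, support, config)

    mask = np.full(img.shape, BACKGROUND, dtype=np.uint8)
    mask[support] = SOLID
    mask[damage] = DAMAGE
    if config.boundary_band_px > 0:
        mask = derive_boundary(mask, config.boundary_band_px)
    return mask


def _crack_pixels(img, support, config) -> np.ndarray:
    inside = img[support]
    crack_t = config.crack_threshold
    auto = crack_t is None
    if auto:
        if np.ptp(inside) == 0:
            return np.zeros_like(support)  # uniform interior: crack-free
        crack_t = threshold_otsu(inside)
    damage = support & (img <= crack_t)
    if auto and damage.any():
        solid_part = support & ~damage
        if not solid_part.any():
            return np.zeros_like(support)
        contrast = img[solid_part].mean() - img[damage].mean()
        if contrast < config.min_contrast:
            return np.zeros_like(support)
    if config.min_speckle_px > 0 and damage.any():
        comps, n = cc_label(damage, connectivity=2, return_num=True)
        sizes = np.bincount(comps.ravel())
        keep = sizes >= config.min_speckle_px
        keep[0] = False
        damage = keep[comps]
    return damage


def derive_boundary(mask: np.ndarray, band_px: int) -> np.ndarray:
    """Grow a boundary band around every solid/damage interface.

    In-object pixels within chessboard distance ``band_px`` of a pixel of
    the opposite class (solid vs damage) are relabeled boundary, on both
    sides of the interface; ``band_px = 0`` returns the mask unchanged.
    The background partition is untouched, so total object pixel count is
    conserved.
    """
    if band_px < 0:
        raise ParameterError("band_px must be non-negative")
    mask = np.asarray(mask, dtype=np.uint8)
    if band_px == 0:
        return mask.copy()
    solid = mask == SOLID
    damage = mask == DAMAGE
    out = mask.copy()
    if not (solid.any() and damage.any()):
        return out
    dist_to_damage = ndimage.distance_transform_cdt(~damage, metric="chessboard")
    dist_to_solid = ndimage.distance_transform_cdt(~solid, metric="chessboard")
    band = (solid & (dist_to_damage <= band_px)) | (damage & (dist_to_solid <= band_px))
    out[band] = BOUNDARY
    return out


class CrackSegmenter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: grayscale sections -> label masks.

    Stateless per-slice thresholding (each section is segmented with its
    own automatically determined thresholds unless fixed ones are given),
    so ``fit`` only validates parameters. ``transform`` accepts a sequence
    of :class:`GrayscaleSlice` or bare 2D uint8/uint16 arrays (assumed
    cracks-dark) and returns a list of uint8 label masks.

    Parameters mirror :class:`SegmentationConfig`.
    """

    def __init__(self, background_threshold=None, crack_threshold=None,
                 min_speckle_px=5, boundary_band_px=0, min_contrast=20.0):
        self.background_threshold = background_threshold
        self.crack_threshold = crack_threshold
        self.min_speckle_px = min_speckle_px
        self.boundary_band_px = boundary_band_px
        self.min_contrast = min_contrast

    def _config(self) -> SegmentationConfig:
        return SegmentationConfig(
            background_threshold=self.background_threshold,
            crack_threshold=self.crack_threshold,
            min_speckle_px=self.min_speckle_px,
            boundary_band_px=self.boundary_band_px,
            min_contrast=self.min_contrast)

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X) -> list[np.ndarray]:
        config = self._config()
        out = []
        for item in _as_slices(X):
            out.append(segment_slice(item, config))
        return out


def _as_slices(X) -> list[GrayscaleSlice]:
    if isinstance(X, (GrayscaleSlice, np.ndarray)):
        X = [X]
    slices = []
    for i, item in enumerate(X):
        if isinstance(item, GrayscaleSlice):
            slices.append(item)
        else:
            slices.append(GrayscaleSlice(pixels=np.asarray(item), slice_index=i))
    return slices
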