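"""Synthetic cross-section phantoms with exact ground truth.

Real seed tomograms cannot ship with a software package, so every
downstream stage is exercised on phantoms: an elliptical seed-like body
(default dimensions taken from measured corn-kernel size ranges, a
12.6 mm x 8.5 mm section) containing thin elongated cracks drawn as
dilated random-walk polylines. Because the cracks are drawn onto a label
mask first and the raster rendered from it, the damage-area fraction of
every slice is known exactly — the ground truth the Monte Carlo
estimator is judged against.

A virtual load scenario (static/dynamic, vertical/horizontal placement,
load expressed as a fraction of the critical force F_kr) sets the target
damage fraction through a configurable monotone dose-response; each of
the 20 sections of a specimen (10 horizontal + 10 vertical) draws an
independent crack field aimed at that target. The generator is a pure
function of (spec, scenario, slice_index, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyDomainError, ParameterError, SizingError
from .imaging import CRACKS_BRIGHT, CRACKS_DARK, GrayscaleSlice, derive_boundary
from .labels import BACKGROUND, BOUNDARY, DAMAGE, SOLID

#: measured corn-kernel dimension ranges, mm (min, max)
KERNEL_LENGTH_MM = (12.09, 13.11)
KERNEL_WIDTH_MM = (8.02, 9.07)
KERNEL_THICKNESS_MM = (4.1, 5.05)

#: sub-critical load grid, as fractions of the critical force F_kr
LOAD_FRACTION_GRID = (0.3, 0.45, 0.6, 0.75, 0.9)

N_SECTIONS = 20  # 10 horizontal + 10 vertical per specimen


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of the synthetic specimen.

    The default body is a 12.6 x 8.5 mm ellipse (kernel length x width,
    mid-range of the measured samples) rasterized at 0.05 mm/px. Cracks
    are random-walk polylines dilated to ``crack_width_px``, clipped to
    an inner margin of the body so internal damage never touches the
    background.
    """

    body_semi_axes: tuple[float, float] = (6.3, 4.25)  # mm (half-width x, half-height y)
    pixel_pitch: float = 0.05                          # mm per pixel
    image_shape: tuple[int, int] = (220, 300)          # (rows, cols)
    crack_count: int | tuple[int, int] = 64            # max cracks per slice (or range)
    crack_width_px: int = 2
    crack_length_frac: float = 0.3     # of the body's major diameter
    boundary_band_px: int = 0
    intensity_solid: int = 200
    intensity_damage: int = 40
    intensity_background: int = 0
    noise_sd: float = 6.0
    polarity: str = CRACKS_DARK
    # test hooks: deterministic geometry instead of random cracks
    fill_body_with_damage: bool = False
    rect_cracks: Optional[Sequence[tuple[int, int, int, int]]] = None  # (r0, c0, h, w)

    def __post_init__(self):
        a_px, b_px = self.semi_axes_px
        rows, cols = self.image_shape
        if 2 * a_px >= cols or 2 * b_px >= rows:
            raise SizingError(
                f"body {2 * a_px:.0f}x{2 * b_px:.0f} px does not fit in "
                f"image {cols}x{rows} at pitch {self.pixel_pitch} mm/px")
        if self.intensity_solid == self.intensity_damage:
            raise ParameterError("intensity_solid must differ from intensity_damage")
        max_cracks = self.max_crack_count
        if self.crack_width_px == 0 and max_cracks > 0:
            raise ParameterError("crack_width_px = 0 with crack_count > 0")
        if self.crack_width_px < 0 or max_cracks < 0:
            raise ParameterError("crack parameters must be non-negative")
        if not (0 < self.crack_length_frac <= 1):
            raise ParameterError("crack_length_frac must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        for name in ("intensity_solid", "intensity_damage", "intensity_background"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ParameterError(f"{name}={v} outside 8-bit range")
        if self.polarity not in (CRACKS_DARK, CRACKS_BRIGHT):
            raise ParameterError(f"unknown polarity {self.polarity!r}")

    @property
    def semi_axes_px(self) -> tuple[float, float]:
        return (self.body_semi_axes[0] / self.pixel_pitch,
                self.body_semi_axes[1] / self.pixel_pitch)

    @property
    def max_crack_count(self) -> int:
        if isinstance(self.crack_count, tuple):
            return int(self.crack_count[1])
        return int(self.crack_count)


@dataclass(frozen=True)
class LoadScenario:
    """Virtual external-load cell of the study grid.

    ``load_fraction`` is the applied force as a fraction of the critical
    force F_kr at which the specimen fully deforms. The damage response
    maps it to a target damage-area fraction: ``baseline_fraction`` at
    0.3 F_kr rising monotonically to ``baseline_fraction * fold_span``
    at 0.9 F_kr, with ``shape`` bending the interpolation (1 = linear).
    Fold spans default to 6.0 for static and 3.0 for dynamic loading —
    the magnitudes reported for real kernels. ``replicate_noise_sd``
    scatters the per-slice target to emulate specimen-to-specimen and
    section-to-section variability.
    """

    load_type: str = "static"          # or "dynamic"
    orientation: str = "vertical"      # placement relative to the load
    load_fraction: float = 0.3         # of F_kr
    baseline_fraction: float = 0.02    # damage fraction at 0.3 F_kr
    fold_span: Optional[float] = None  # damage at 0.9 F_kr / baseline
    shape: float = 1.0
    replicate_noise_sd: float = 0.0

    def __post_init__(self):
        if self.load_type not in ("static", "dynamic"):
            raise ParameterError(f"unknown load_type {self.load_type!r}")
        if self.orientation not in ("vertical", "horizontal"):
            raise ParameterError(f"unknown orientation {self.orientation!r}")
        if not (0 < self.load_fraction <= 1):
            raise ParameterError("load_fraction must lie in (0, 1]")
        if not (0 <= self.baseline_fraction <= 1):
            raise ParameterError("baseline_fraction must lie in [0, 1]")
        if self.resolved_fold_span < 1:
            raise ParameterError("fold_span must be >= 1")
        if self.shape <= 0:
            raise ParameterError("shape must be positive")
        if self.replicate_noise_sd < 0:
            raise ParameterError("replicate_noise_sd must be non-negative")

    @property
    def resolved_fold_span(self) -> float:
        if self.fold_span is not None:
            return float(self.fold_span)
        return 6.0 if self.load_type == "static" else 3.0


@dataclass(frozen=True)
class GroundTruth:
    """Exact pixel tallies of one phantom slice."""

    area_object_px: int
    area_damage_px: int
    area_boundary_px: int

    def __post_init__(self):
        if self.area_object_px <= 0:
            raise EmptyDomainError("ground truth requires a non-empty object")
        if self.area_damage_px + self.area_boundary_px > self.area_object_px:
            raise ParameterError("damage + boundary exceed object area")

    @property
    def weighted_fraction(self) -> float:
        """(damage + boundary/2) / object — the exact-area damage coefficient."""
        return (self.area_damage_px + 0.5 * self.area_boundary_px) / self.area_object_px

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "GroundTruth":
        m = np.asarray(mask)
        obj = int(np.count_nonzero(m != BACKGROUND))
        if obj == 0:
            raise EmptyDomainError("mask contains no object pixels")
        return cls(area_object_px=obj,
                   area_damage_px=int(np.count_nonzero(m == DAMAGE)),
                   area_boundary_px=int(np.count_nonzero(m == BOUNDARY)))


def exact_damage_fraction(mask: np.ndarray) -> float:
    """Exact weighted damage-area fraction of a label mask.

    The brute-force pixel-counting oracle the Monte Carlo estimator is
    unbiased for: (damage + 0.5 * boundary) / object pixels.
    """
    return GroundTruth.from_mask(mask).weighted_fraction


def damage_response(scenario: LoadScenario) -> float:
    """Target damage-area fraction for a load scenario.

    Monotone non-decreasing in load_fraction; equals the baseline at
    0.3 F_kr and baseline * fold_span at 0.9 F_kr. Between those anchors
    the fold factor is interpolated as 1 + (fold - 1) * t**shape with
    t the normalized position in [0.3, 0.9]; outside them it clamps.
    """
    fold = scenario.resolved_fold_span
    lo, hi = LOAD_FRACTION_GRID[0], LOAD_FRACTION_GRID[-1]
    t = np.clip((scenario.load_fraction - lo) / (hi - lo), 0.0, 1.0)
    factor = 1.0 + (fold - 1.0) * t ** scenario.shape
    return float(min(1.0, scenario.baseline_fraction * factor))


# ---------------------------------------------------------------------------
# slice generation

def _body_mask(spec: PhantomSpec, shrink_px: float = 0.0) -> np.ndarray:
    rows, cols = spec.image_shape
    a, b = spec.semi_axes_px
    a, b = a - shrink_px, b - shrink_px
    if a <= 1 or b <= 1:
        return np.zeros(spec.image_shape, dtype=bool)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.ogrid[:rows, :cols]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _stamp(damage: np.ndarray, allowed: np.ndarray, r: float, c: float,
           width: int) -> int:
    """Stamp a width x width square at (r, c); return newly set pixels."""
    r0 = int(round(r)) - width // 2
    c0 = int(round(c)) - width // 2
    r0, c0 = max(r0, 0), max(c0, 0)
    win_d = damage[r0:r0 + width, c0:c0 + width]
    win_a = allowed[r0:r0 + width, c0:c0 + width]
    new = win_a & ~win_d
    n = int(np.count_nonzero(new))
    if n:
        win_d |= new
    return n


def _walk_crack(rng: np.random.Generator, damage: np.ndarray,
                inner: np.ndarray, inner_coords: np.ndarray,
                spec: PhantomSpec, budget: int) -> int:
    """Draw one dilated random-walk crack; stop early once budget pixels added."""
    a, b = spec.semi_axes_px
    length = max(spec.crack_width_px + 1,
                 int(round(spec.crack_length_frac * 2 * max(a, b))))
    start = inner_coords[rng.integers(len(inner_coords))]
    r, c = float(start[0]), float(start[1])
    theta = rng.uniform(0.0, 2.0 * np.pi)
    added = 0
    for _ in range(length):
        added += _stamp(damage, inner, r, c, spec.crack_width_px)
        if added >= budget:
            break
        theta += rng.normal(0.0, 0.15)  # tortuosity of the polyline
        r += np.sin(theta)
        c += np.cos(theta)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < inner.shape[0] and 0 <= ci < inner.shape[1]) or not inner[ri, ci]:
            break  # crack reached the body margin
    return added


def _draw_damage(rng: np.random.Generator, spec: PhantomSpec,
                 body: np.ndarray, target_px: int) -> np.ndarray:
    """Accumulate crack pixels until the exact-area target is met."""
    damage = np.zeros_like(body)
    if target_px <= 0 or spec.max_crack_count == 0:
        return damage
    # keep cracks off the rim so hole-filling can recover the full support
    margin = spec.crack_width_px + spec.boundary_band_px + 2
    inner = _body_mask(spec, shrink_px=margin)
    if not inner.any():
        return damage
    inner_coords = np.argwhere(inner)
    if isinstance(spec.crack_count, tuple):
        max_cracks = int(rng.integers(spec.crack_count[0], spec.crack_count[1] + 1))
    else:
        max_cracks = int(spec.crack_count)
    tally = 0
    for _ in range(max_cracks):
        if tally >= target_px:
            break
        tally += _walk_crack(rng, damage, inner, inner_coords, spec,
                             budget=target_px - tally)
    return damage


def generate_slice(spec: PhantomSpec, scenario: LoadScenario,
                   slice_index: int, seed: int
                   ) -> tuple[GrayscaleSlice, np.ndarray, GroundTruth]:
    """Generate one phantom cross-section.

    Returns the rendered grayscale slice, its label mask and the exact
    ground-truth tallies. Deterministic: the per-slice random stream is
    seeded with ``seed + slice_index``, so identical inputs reproduce
    identical outputs bit for bit.
    """
    if not (0 <= slice_index < N_SECTIONS):
        raise ParameterError(f"slice_index {slice_index} outside [0, {N_SECTIONS - 1}]")
    if seed < 0:
        raise ParameterError("seed must be non-negative")
    rng = np.random.default_rng(seed + slice_index)

    body = _body_mask(spec)
    if not body.any():
        raise SizingError("body ellipse rasterized to zero pixels")

    if spec.fill_body_with_damage:
        damage = body.copy()
    elif spec.rect_cracks is not None:
        damage = np.zeros_like(body)
        for r0, c0, h, w in spec.rect_cracks:
            damage[r0:r0 + h, c0:c0 + w] = True
        damage &= body
    else:
        target = damage_response(scenario)
        if scenario.replicate_noise_sd > 0:
            target = float(np.clip(
                target + rng.normal(0.0, scenario.replicate_noise_sd), 0.0, 1.0))
        target_px = int(round(target * np.count_nonzero(body)))
        damage = _draw_damage(rng, spec, body, target_px)

    mask = np.full(spec.image_shape, BACKGROUND, dtype=np.uint8)
    mask[body] = SOLID
    mask[damage] = DAMAGE

    raster = np.full(spec.image_shape, float(spec.intensity_background))
    raster[body] = spec.intensity_solid
    raster[damage] = spec.intensity_damage
    if spec.noise_sd > 0:
        raster += rng.normal(0.0, spec.noise_sd, size=raster.shape)
    raster = np.clip(np.rint(raster), 0, 255).astype(np.uint8)
    if spec.polarity == CRACKS_BRIGHT:
        raster = (255 - raster).astype(np.uint8)

    if spec.boundary_band_px > 0:
        mask = derive_boundary(mask, spec.boundary_band_px)

    orientation = "horizontal" if slice_index < N_SECTIONS // 2 else "vertical"
    slc = GrayscaleSlice(pixels=raster, slice_index=slice_index,
                         orientation=orientation, pixel_pitch=spec.pixel_pitch,
                         polarity=spec.polarity)
    return slc, mask, GroundTruth.from_mask(mask)


@dataclass(frozen=True)
class PhantomStack:
    """A full 20-section phantom specimen."""

    slices: tuple[GrayscaleSlice, ...]
    masks: tuple[np.ndarray, ...]
    truths: tuple[GroundTruth, ...]
    spec: PhantomSpec
    scenario: LoadScenario
    seed: int

    @property
    def mean_weighted_fraction(self) -> float:
        return float(np.mean([t.weighted_fraction for t in self.truths]))


def generate_stack(spec: PhantomSpec, scenario: LoadScenario,
                   seed: int) -> PhantomStack:
    """Generate all 20 sections of a specimen (indices 0-9 horizontal,
    10-19 vertical); per-slice damage fractions scatter around the
    scenario's damage response with spread replicate_noise_sd."""
    slices, masks, truths = [], [], []
    for i in range(N_SECTIONS):
        slc, mask, truth = generate_slice(spec, scenario, i, seed)
        slices.append(slc)
        masks.append(mask)
        truths.append(truth)
    return PhantomStack(slices=tuple(slices), masks=tuple(masks),
                        truths=tuple(truths), spec=spec, scenario=scenario,
                        seed=seed)


# ---------------------------------------------------------------------------
# on-disk stack format

def write_stack(stack: PhantomStack, out_dir, image_format: str = "tiff") -> Path:
    """Write a phantom stack as loose image files plus a JSON manifest.

    Slices go to 8-bit grayscale TIFF (default) or PNG, masks to
    single-channel label TIFFs (codes 0..3), exact tallies to
    ``ground_truth.csv``. Returns the manifest path.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "png": "png"}.get(image_format)
    if ext is None:
        raise ParameterError(f"unsupported image format {image_format!r}")

    entries = []
    for slc, mask in zip(stack.slices, stack.masks):
        img_name = f"slice_{slc.slice_index:02d}.{ext}"
        mask_name = f"mask_{slc.slice_index:02d}.tif"
        _write_gray(out_dir / img_name, slc.pixels)
        _write_gray(out_dir / mask_name, mask)
        entries.append({"file": img_name, "mask": mask_name,
                        "slice_index": slc.slice_index,
                        "orientation": slc.orientation})

    gt = pd.DataFrame([{
        "slice_index": slc.slice_index,
        "area_object_px": t.area_object_px,
        "area_damage_px": t.area_damage_px,
        "area_boundary_px": t.area_boundary_px,
        "weighted_fraction": t.weighted_fraction,
    } for slc, t in zip(stack.slices, stack.truths)])
    gt.to_csv(out_dir / "ground_truth.csv", index=False)

    manifest = {
        "pixel_pitch": stack.spec.pixel_pitch,
        "polarity": stack.spec.polarity,
        "seed": stack.seed,
        "scenario": {
            "load_type": stack.scenario.load_type,
            "orientation": stack.scenario.orientation,
            "load_fraction": stack.scenario.load_fraction,
        },
        "ground_truth": "ground_truth.csv",
        "slices": entries,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path


def _write_gray(path: Path, pixels: np.ndarray) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, pixels)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, pixels)


def default_scenarios(baseline_fraction: float = 0.02,
                      static_fold: float = 6.0, dynamic_fold: float = 3.0,
                      replicate_noise_sd: float = 0.0,
                      load_fractions: Sequence[float] = LOAD_FRACTION_GRID
                      ) -> list[LoadScenario]:
    """The full factor grid: 2 load types x 2 orientations x 5 load fractions."""
    return [LoadScenario(load_type=lt, orientation=ori, load_fraction=f,
                         baseline_fraction=baseline_fraction,
                         fold_span=static_fold if lt == "static" else dynamic_fold,
                         replicate_noise_sd=replicate_noise_sd)
            for lt in ("static", "dynamic")
            for ori in ("vertical", "horizontal")
            for f in load_fractions]
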