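"""Blood-stain image analysis: segmentation and the S-index.

A dried blood stain on chromatography paper consists of a roughly circular
footprint.  When insoluble deoxy-HbS polymers are present they are trapped at
the deposition point and form a dark center spot, while soluble hemoglobin
wicks outward into a diffuse pink peripheral ring.  The *S-index* quantifies
this pattern as

    S = mean(255 − B | center spot) / mean(255 − B | peripheral ring)

where B is the blue channel of the scanned 8-bit RGB image; 255 − B is the
"red color intensity".  Uniform stains (no HbS) give S ≈ 1, dark-centered
stains give S > 1.

Segmentation is intentionally simple and uses only the quantity the S-index
is built on:

1. foreground = largest connected component after Otsu thresholding of 255 − B;
2. stain center = foreground centroid;
3. radial red-intensity profile in 1-px annular bins;
4. center/ring boundary = radius of the steepest profile drop when a dark
   spot exists, otherwise a fixed fraction (default 0.35) of the footprint
   radius so that negative stains still get a well-defined partition.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Any, Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import (
    AmbiguousStain,
    DegenerateInputError,
    FormatError,
    NoStainFound,
    SegmentationError,
    ValidationError,
)

#: Smallest image edge accepted.
MIN_IMAGE_EDGE = 32

#: Minimum connected-component area (px) to count as a stain footprint.
MIN_STAIN_AREA = 500

#: Minimum pixels per mask.
MIN_MASK_PIXELS = 50

#: Fallback center radius as a fraction of the footprint radius when no
#: dark-spot edge is detected (negative stains).
DEFAULT_CENTER_FRACTION = 0.35

#: Minimum radial-profile drop (red-intensity units per 1-px bin step) that
#: counts as a center-spot edge.
DEFAULT_DROP_THRESHOLD = 8.0


@dataclass
class StainImage:
    """An 8-bit RGB raster of a single blood stain plus provenance metadata."""

    pixels: np.ndarray
    resolution: float | None = None  # pixels per mm, if known
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError("pixels must be an H x W x 3 raster")
        if px.dtype != np.uint8:
            raise ValidationError("pixels must be 8-bit (uint8)")
        if px.shape[0] < MIN_IMAGE_EDGE or px.shape[1] < MIN_IMAGE_EDGE:
            raise ValidationError(f"image must be at least {MIN_IMAGE_EDGE} px on each edge")
        self.pixels = px

    @property
    def blue(self) -> np.ndarray:
        """The blue channel B; the only channel the S-index depends on."""
        return self.pixels[:, :, 2]

    @property
    def red_intensity(self) -> np.ndarray:
        """Red color intensity 255 − B as float."""
        return 255.0 - self.blue.astype(np.float64)


@dataclass
class StainSegmentation:
    """Disjoint boolean masks for the center spot and peripheral ring."""

    center_mask: np.ndarray
    ring_mask: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.center_mask, bool)
        r = np.asarray(self.ring_mask, bool)
        if c.shape != r.shape:
            raise ValidationError("masks must have identical shapes")
        if np.any(c & r):
            raise ValidationError("center and ring masks must be disjoint")
        if c.sum() < MIN_MASK_PIXELS or r.sum() < MIN_MASK_PIXELS:
            raise ValidationError(f"each mask needs at least {MIN_MASK_PIXELS} pixels")
        self.center_mask = c
        self.ring_mask = r


@dataclass(frozen=True)
class SIndexResult:
    """S-index and the two regional mean red intensities it is built from."""

    s_index: float
    center_mean_red: float
    ring_mean_red: float


def load_image(path: str | pathlib.Path) -> StainImage:
    """Load a PNG or TIFF stain scan as an 8-bit RGB :class:`StainImage`.

    16-bit inputs are rescaled to 8 bits by dividing by 257 and rounding to
    nearest (65535 → 255).  Grayscale, alpha-bearing, or corrupt files raise
    :class:`FormatError`.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - any decode failure is a format error
        raise FormatError(f"cannot decode {path.name}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path.name}: expected 3-channel RGB, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        pixels = arr
    elif arr.dtype == np.uint16:
        pixels = np.rint(arr / 257.0).astype(np.uint8)
    else:
        raise FormatError(f"{path.name}: unsupported dtype {arr.dtype}")
    try:
        return StainImage(pixels=pixels, metadata={"source": str(path)})
    except ValidationError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc


def write_image(image: StainImage, path: str | pathlib.Path) -> None:
    """Write an image as 8-bit RGB PNG (lossless)."""
    iio.imwrite(pathlib.Path(path), image.pixels)


def _radial_profile(
    red: np.ndarray, valid: np.ndarray, dist: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean red intensity in 1-px annular bins over ``valid`` pixels."""
    r_bin = dist[valid].astype(np.int64)
    weights = red[valid]
    n_bins = int(r_bin.max()) + 1 if r_bin.size else 0
    sums = np.bincount(r_bin, weights=weights, minlength=n_bins)
    counts = np.bincount(r_bin, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = sums / counts
    return profile, counts


def segment_stain(
    image: StainImage,
    min_area: int = MIN_STAIN_AREA,
    center_fraction: float = DEFAULT_CENTER_FRACTION,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> StainSegmentation:
    """Segment one stain into center-spot and peripheral-ring masks.

    Raises
    ------
    NoStainFound
        No connected foreground component of at least ``min_area`` pixels.
    AmbiguousStain
        A second component at least half the size of the largest.
    """
    red = image.red_intensity
    if float(red.max() - red.min()) < 5.0:
        raise NoStainFound("image is uniform; no stain against background")
    threshold = threshold_otsu(red)
    foreground = red > threshold

    labels = label(foreground, connectivity=2)
    if labels.max() == 0:
        raise NoStainFound("no foreground component")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1]
    if sizes[order[0]] < min_area:
        raise NoStainFound(
            f"largest component has {sizes[order[0]]} px < minimum {min_area}"
        )
    if len(order) > 1 and sizes[order[1]] >= 0.5 * sizes[order[0]]:
        raise AmbiguousStain("multiple comparable foreground components")
    footprint = labels == order[0]

    # Scanner clipping biases regional means: drop saturated red (B == 0) and
    # pure-white pixels from the analysis masks.
    px = image.pixels
    white = (px[:, :, 0] == 255) & (px[:, :, 1] == 255) & (px[:, :, 2] == 255)
    valid = footprint & ~white & (image.blue > 0)
    if valid.sum() < min_area:
        raise NoStainFound("too few unsaturated stain pixels")

    rows, cols = np.nonzero(footprint)
    cy, cx = rows.mean(), cols.mean()
    yy, xx = np.indices(red.shape)
    dist = np.hypot(yy - cy, xx - cx)
    footprint_radius = float(np.sqrt(footprint.sum() / np.pi))

    profile, counts = _radial_profile(red, valid, dist)
    # Search for the steepest drop between consecutive populated bins well
    # inside the footprint (outer 20% excluded: the rim itself is a drop).
    limit = int(0.8 * footprint_radius)
    boundary_radius = center_fraction * footprint_radius
    best_drop = 0.0
    for i in range(min(limit, len(profile) - 1)):
        if counts[i] == 0 or counts[i + 1] == 0:
            continue
        drop = profile[i] - profile[i + 1]
        if drop > best_drop:
            best_drop = drop
            if drop >= drop_threshold:
                boundary_radius = float(i + 1)
    if best_drop < drop_threshold:
        boundary_radius = center_fraction * footprint_radius

    center_mask = valid & (dist <= boundary_radius)
    ring_mask = valid & (dist > boundary_radius)
    if center_mask.sum() < MIN_MASK_PIXELS or ring_mask.sum() < MIN_MASK_PIXELS:
        raise SegmentationError("center/ring partition produced a mask below minimum size")
    return StainSegmentation(center_mask=center_mask, ring_mask=ring_mask)


def s_index(image: StainImage, seg: StainSegmentation) -> SIndexResult:
    """Compute the S-index for a segmented stain.

    Only the blue channel enters: S = mean(255 − B | center) / mean(255 − B | ring).
    """
    if seg.center_mask.shape != image.pixels.shape[:2]:
        raise ValidationError("segmentation does not match image shape")
    red = image.red_intensity
    center_mean = float(red[seg.center_mask].mean())
    ring_mean = float(red[seg.ring_mask].mean())
    if ring_mean == 0.0:
        raise DegenerateInputError("ring mean red intensity is zero")
    return SIndexResult(
        s_index=center_mean / ring_mean,
        center_mean_red=center_mean,
        ring_mean_red=ring_mean,
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def analyze_image(image: StainImage, **segment_kwargs: Any) -> SIndexResult:
    """Segment a stain and compute its S-index in one step."""
    return s_index(image, segment_stain(image, **segment_kwargs))


def analyze_batch(
    image_dir: str | pathlib.Path,
    output_csv: str | pathlib.Path | None = None,
    patterns: Iterable[str] = ("*.png", "*.tif", "*.tiff"),
) -> pd.DataFrame:
    """Analyze every stain image in a directory.

    Returns one row per image, ordered by filename.  Images that fail to
    load or segment are reported as flagged rows (``flag`` holds the error
    class name), never silently dropped.
    """
    image_dir = pathlib.Path(image_dir)
    paths: list[pathlib.Path] = []
    for pat in patterns:
        paths.extend(image_dir.glob(pat))
    paths = sorted(set(paths))
    if not paths:
        raise ValidationError(f"no images found in {image_dir}")

    rows = []
    for path in paths:
        row: dict[str, Any] = {
            "stain_id": path.stem,
            "s_index": np.nan,
            "center_mean_red": np.nan,
            "ring_mean_red": np.nan,
            "flag": "",
        }
        try:
            result = analyze_image(load_image(path))
        except (FormatError, SegmentationError, DegenerateInputError) as exc:
            row["flag"] = type(exc).__name__
        else:
            row.update(
                s_index=result.s_index,
                center_mean_red=result.center_mean_red,
                ring_mean_red=result.ring_mean_red,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if output_csv is not None:
        table.to_csv(output_csv, index=False)
    return table
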