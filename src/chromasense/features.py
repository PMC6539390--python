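"""Spot localization and DeltaRGB feature extraction from sensor-array images.

Pipeline per image pair: channel-max grayscale -> 3x3 median filter ->
Otsu threshold -> morphological opening then closing; connected components
give the 12 spot centers; a 15-px circular ROI around each center yields
per-channel gray means, and the feature is the signed post-minus-pre
difference per spot and channel (36 values, dye-major, channels R,G,B).

The sign convention Delta = after - before is fixed here and recorded in
output metadata; only the visualization map takes absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology

from .synthetic import CHANNELS, N_FEATURES, ImagePair, SensorLayout

__all__ = [
    "ExtractionConfig",
    "SpotROI",
    "FeatureVector",
    "NoSpotsError",
    "SpotCountError",
    "preprocess",
    "locate_spots",
    "roi_mean_rgb",
    "extract_features",
    "difference_map",
]

SIGN_CONVENTION = "after_minus_before"


class NoSpotsError(ValueError):
    """Preprocessing found no spot foreground."""


class SpotCountError(ValueError):
    """Connected-component count differs from the expected grid size."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(
            f"found {found} spot components, expected {expected}; "
            "supply a layout hint to enable grid-registration fallback")


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable preprocessing/extraction parameters.

    The operations are fixed (median, Otsu, opening+closing); sizes are
    free parameters: 3x3 median, structuring-disc radius 3, ROI radius 15.
    """

    roi_radius: float = 15.0
    median_size: int = 3
    morph_radius: int = 3


@dataclass(frozen=True)
class SpotROI:
    """Circular region of interest around one dye spot.

    center is (x, y) in pixel coordinates; membership is the inclusive
    disc (x-cx)^2 + (y-cy)^2 <= r^2 over integer pixel centers.
    """

    center: tuple[float, float]
    radius: float = 15.0
    dye_label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class FeatureVector:
    """The 36 signed gray-level differences with their <dye>:<channel> names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,) or len(self.names) != N_FEATURES:
            raise ValueError(f"feature vector must have {N_FEATURES} entries")
        if np.any(np.abs(v) > 255):
            raise ValueError("gray-level differences cannot exceed 255")
        self.values = v


def preprocess(image: np.ndarray,
               config: ExtractionConfig = ExtractionConfig()) -> np.ndarray:
    """Segment spot foreground from an 8-bit RGB sensor image.

    Returns a boolean mask; raises :class:`NoSpotsError` when no
    foreground survives (e.g. a uniform image, where no threshold
    separates spots from background).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    gray = img.max(axis=2).astype(np.uint8)
    footprint = np.ones((config.median_size, config.median_size), dtype=bool)
    gray = filters.median(gray, footprint=footprint)
    if gray.min() == gray.max():
        raise NoSpotsError("uniform image: no spots found")
    mask = gray > filters.threshold_otsu(gray)
    disc = morphology.disk(config.morph_radius)
    mask = morphology.opening(mask, disc)
    mask = morphology.closing(mask, disc)
    if not mask.any():
        raise NoSpotsError("no spot foreground after morphology")
    return mask


def _order_row_major(centers: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Sort (x, y) centers into row-major grid order."""
    order = np.argsort(centers[:, 1], kind="stable")
    out = []
    for r in range(rows):
        chunk = order[r * cols:(r + 1) * cols]
        out.extend(chunk[np.argsort(centers[chunk, 0], kind="stable")])
    return np.asarray(out)


def locate_spots(mask: np.ndarray,
                 layout_hint: SensorLayout | None = None,
                 roi_radius: float = 15.0) -> list[SpotROI]:
    """Locate the 12 spot centers (component centroids, row-major order).

    When the component count differs from the grid size, falls back to
    grid registration against the layout hint: each hinted center takes
    the nearest detected centroid within half the render radius, or the
    hinted position itself if none is close enough (a weak spot can
    vanish entirely at thresholding).
    """
    layout = layout_hint if layout_hint is not None else SensorLayout()
    expected = layout.grid_rows * layout.grid_cols
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    centers = np.array([(p.centroid[1], p.centroid[0]) for p in props])

    if len(props) != expected:
        if layout_hint is None:
            raise SpotCountError(found=len(props), expected=expected)
        tol = layout.spot_radius_render
        hinted = np.asarray(layout.spot_centers, dtype=float)
        resolved = []
        for hx, hy in hinted:
            if len(centers):
                d = np.hypot(centers[:, 0] - hx, centers[:, 1] - hy)
                j = int(np.argmin(d))
                resolved.append(tuple(centers[j]) if d[j] <= tol else (hx, hy))
            else:
                resolved.append((hx, hy))
        ordered = np.asarray(resolved)
    else:
        ordered = centers[_order_row_major(centers, layout.grid_rows,
                                           layout.grid_cols)]

    return [SpotROI(center=(float(x), float(y)), radius=roi_radius,
                    dye_label=layout.dye_names[i])
            for i, (x, y) in enumerate(ordered)]


def roi_mean_rgb(image: np.ndarray, roi: SpotROI) -> tuple[float, float, float]:
    """Mean R, G, B gray levels over the inclusive disc of the ROI.

    Membership is exact: all integer pixel centers with
    (x-cx)^2 + (y-cy)^2 <= r^2.  A disc clipped by the image border is an
    error (a partial ROI would bias the mean).
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    cx, cy = roi.center
    r = roi.radius
    if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
        raise ValueError(f"ROI disc at {roi.center} clipped by image border")
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
    patch = img[y0:y1 + 1, x0:x1 + 1].astype(float)
    means = patch[inside].mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def extract_features(pair: ImagePair,
                     config: ExtractionConfig = ExtractionConfig()) -> FeatureVector:
    """Compute the 36 signed DeltaR/DeltaG/DeltaB features of an image pair.

    Spots are located on the pre-exposure image (the array geometry does
    not move during exposure) and the same ROIs are read on both images.
    """
    rois = _pair_rois(pair, config)
    layout = pair.layout_hint if pair.layout_hint is not None else SensorLayout()
    values = np.empty(N_FEATURES)
    names = []
    for i, roi in enumerate(rois):
        pre = roi_mean_rgb(pair.before, roi)
        post = roi_mean_rgb(pair.after, roi)
        for c in range(3):
            values[3 * i + c] = post[c] - pre[c]
            names.append(f"{layout.dye_names[i]}:{CHANNELS[c]}")
    return FeatureVector(values=values, names=tuple(names))


def _pair_rois(pair: ImagePair, config: ExtractionConfig) -> list[SpotROI]:
    mask = preprocess(pair.before, config)
    return locate_spots(mask, layout_hint=pair.layout_hint,
                        roi_radius=config.roi_radius)


def difference_map(pair: ImagePair,
                   config: ExtractionConfig = ExtractionConfig()) -> np.ndarray:
    """Render the normalized |Delta| feature graph (visualization only).

    |DeltaR|,|DeltaG|,|DeltaB| are min-max normalized to [0, 255] jointly
    across all 36 components and painted into the spot discs on black.
    Model inputs always use the raw signed values, never this map.
    """
    fv = extract_features(pair, config)
    rois = _pair_rois(pair, config)
    absd = np.abs(fv.values).reshape(-1, 3)
    lo, hi = absd.min(), absd.max()
    scaled = np.zeros_like(absd) if hi == lo else (absd - lo) / (hi - lo) * 255
    h, w = pair.before.shape[:2]
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for roi, color in zip(rois, scaled):
        cx, cy = roi.center
        yy, xx = np.ogrid[:h, :w]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= roi.radius ** 2
        out[disc] = np.rint(color).astype(np.uint8)
    return out
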