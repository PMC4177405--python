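"""Somatic brightness and labeled-fraction quantification in fixed tissue.

Somata are segmented as bright blobs at the expected soma scale; each
detection gets a nucleus-excluded ring mask (healthy cytosolic GCaMP is
absent from the nucleus), and somatic brightness is the mean over the
ring pixels.  Brightness values are normalized by the mean brightness of
fluorescent beads of known size imaged under the same conditions, which
removes session-to-session illumination differences.  The labeled
fraction is the fraction of counterstained (red, NeuN-like) somata with
a labeled (green) soma nearby.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import math

from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import DegenerateDataError, InvalidRoiError, NormalizationError

__all__ = [
    "SomaSegment",
    "BoxStats",
    "segment_somata",
    "somatic_brightness",
    "detect_beads",
    "bead_normalize",
    "colabel_fraction",
    "box_stats",
]


@dataclass
class SomaSegment:
    """One segmented soma: center (pixels) and nucleus-excluded ring mask."""

    center: tuple[float, float]  # (row, col) pixels
    ring_mask: np.ndarray  # boolean (H, W)
    brightness_raw: float = np.nan
    brightness_normalized: float = np.nan


@dataclass
class BoxStats:
    """Box-and-whisker summary: quartile box, 1.5 IQR whiskers clamped to
    the most extreme samples inside range, outliers beyond."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


def _ring_mask(
    center: tuple[float, float],
    nucleus_radius_px: float,
    soma_radius_px: float,
    shape: tuple[int, int],
) -> np.ndarray:
    yy, xx = np.meshgrid(
        np.arange(shape[0]) + 0.5, np.arange(shape[1]) + 0.5, indexing="ij"
    )
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (d2 < soma_radius_px**2) & (d2 >= nucleus_radius_px**2)


def segment_somata(
    image: np.ndarray,
    soma_radius_px: float,
    nucleus_radius_px: float,
    seed_points: np.ndarray | None = None,
    threshold: float | None = None,
    match_radius_px: float | None = None,
) -> list[SomaSegment]:
    """Detect somata in a single-channel image; deterministic given inputs.

    Detection is matched filtering at the expected soma scale: the image
    is convolved with a normalized disk of one soma radius.  A disk mean
    is maximal exactly at a soma's center (shifting the disk off a ring
    or filled soma can only lose soma pixels), so each soma — ring-shaped
    or filled — becomes a single center-peaked blob; a Gaussian blur, by
    contrast, peaks on an off-center crest for rings.  The response map
    is thresholded robustly (median plus the larger of 5 robust noise SDs
    and 5% of the dynamic range — somatic brightness spans an order of
    magnitude across cells, so a bimodal-histogram threshold would drop
    the dim tail) and local maxima separated by at least one soma radius
    become soma centers, refined to the local response centroid.  Each
    center gets an annular (nucleus-excluded) ring mask between
    ``nucleus_radius_px`` and ``soma_radius_px``.  Explicit
    ``seed_points`` (N x 2, row/col pixels) bypass detection and force
    one segment each — the hook for manual analyst clicks.  A blank
    image yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidRoiError("segment_somata expects a single-channel 2-D image")
    shape = image.shape

    def make(center: tuple[float, float]) -> SomaSegment:
        mask = _ring_mask(center, nucleus_radius_px, soma_radius_px, shape)
        return SomaSegment(center=center, ring_mask=mask)

    if seed_points is not None:
        return [make((float(r), float(c))) for r, c in np.atleast_2d(seed_points)]

    if match_radius_px is None:
        match_radius_px = soma_radius_px
    k = int(math.ceil(match_radius_px))
    ky, kx = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1), indexing="ij")
    kernel = (ky**2 + kx**2 <= match_radius_px**2).astype(float)
    kernel /= kernel.sum()
    smoothed = fftconvolve(image, kernel, mode="same")
    span = np.ptp(smoothed)
    med = float(np.median(smoothed))
    if span == 0 or span < 1e-6 * max(1.0, abs(med)):
        return []
    if threshold is None:
        mad_sigma = 1.4826 * float(np.median(np.abs(smoothed - med)))
        threshold = med + max(5.0 * mad_sigma, 0.05 * (float(smoothed.max()) - med))
    peaks = peak_local_max(
        smoothed,
        min_distance=max(2, int(round(soma_radius_px))),
        threshold_abs=threshold,
        exclude_border=False,
    )
    # refine each peak to the intensity centroid of its neighborhood
    yy, xx = np.meshgrid(np.arange(shape[0]) + 0.5, np.arange(shape[1]) + 0.5,
                         indexing="ij")
    segments = []
    for r, c in peaks:
        d2 = (yy - (r + 0.5)) ** 2 + (xx - (c + 0.5)) ** 2
        disk = d2 < nucleus_radius_px**2
        w = np.clip(smoothed[disk] - threshold, 0, None)
        if w.sum() > 0:
            center = (float((yy[disk] * w).sum() / w.sum()),
                      float((xx[disk] * w).sum() / w.sum()))
        else:
            center = (r + 0.5, c + 0.5)
        segments.append(make(center))
    return segments


def somatic_brightness(segment: SomaSegment, image: np.ndarray) -> float:
    """Mean pixel value over the segment's ring mask; stored on the segment."""
    if segment.ring_mask.shape != image.shape:
        raise InvalidRoiError("segment mask does not match image shape")
    if not segment.ring_mask.any():
        raise InvalidRoiError("segment has an empty ring mask")
    value = float(image[segment.ring_mask].mean())
    segment.brightness_raw = value
    return value


def detect_beads(
    bead_image: np.ndarray,
    bead_radius_px: float,
    tolerance: float = 0.6,
    interior_fraction: float = 0.8,
) -> list[np.ndarray]:
    """Detect bright disks of the expected bead size; returns their masks.

    Thresholded components within ``tolerance``-fold of the nominal bead
    area pass the size filter (beads are a physical standard of known
    diameter, so the filter rejects debris and merged blobs).  The
    returned measurement mask for each bead is a disk of
    ``interior_fraction`` times the known radius at the component's
    centroid: the thresholded component includes blurred halo pixels
    outside the bead, which would bias the brightness mean downward.
    """
    image = np.asarray(bead_image, dtype=float)
    smoothed = ndimage.gaussian_filter(image, max(1.0, bead_radius_px / 2.0))
    if np.ptp(smoothed) == 0:
        return []
    thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    if not binary.any() or binary.all():
        return []
    labels = label(binary)
    area = np.pi * bead_radius_px**2
    yy, xx = np.meshgrid(
        np.arange(image.shape[0]) + 0.5, np.arange(image.shape[1]) + 0.5,
        indexing="ij",
    )
    masks = []
    for prop in regionprops(labels):
        if not (1 - tolerance) * area <= prop.area <= (1 + tolerance) * area * 2:
            continue
        cy, cx = prop.centroid
        d2 = (yy - (cy + 0.5)) ** 2 + (xx - (cx + 0.5)) ** 2
        disk = d2 < (interior_fraction * bead_radius_px) ** 2
        if disk.any():
            masks.append(disk)
    return masks


def bead_normalize(
    brightness_raw: np.ndarray,
    bead_image: np.ndarray,
    bead_radius_px: float,
) -> np.ndarray:
    """Divide raw brightness by the mean detected-bead brightness.

    Removes global illumination scale exactly: scaling cells and beads
    by a common factor leaves the output unchanged.  Raises when no bead
    is detected.
    """
    masks = detect_beads(bead_image, bead_radius_px)
    if not masks:
        raise NormalizationError("no beads detected; cannot normalize brightness")
    bead_means = [float(np.asarray(bead_image, dtype=float)[m].mean()) for m in masks]
    return np.asarray(brightness_raw, dtype=float) / float(np.mean(bead_means))


def colabel_fraction(
    green_segments: list[SomaSegment],
    red_segments: list[SomaSegment],
    match_radius_px: float,
) -> float:
    """Fraction of red (counterstained) somata with a matched green soma.

    Greedy one-to-one matching by ascending center distance; a red soma
    counts as labeled when its matched green center is within
    ``match_radius_px``.  Raises on an empty red set (the denominator).
    """
    if len(red_segments) == 0:
        raise DegenerateDataError("no red somata; labeled fraction undefined")
    if len(green_segments) == 0:
        return 0.0
    red = np.array([s.center for s in red_segments], dtype=float)
    green = np.array([s.center for s in green_segments], dtype=float)
    d = np.sqrt(((red[:, None, :] - green[None, :, :]) ** 2).sum(axis=2))
    pairs = [
        (d[i, j], i, j)
        for i in range(d.shape[0])
        for j in range(d.shape[1])
        if d[i, j] <= match_radius_px
    ]
    pairs.sort()
    used_red: set[int] = set()
    used_green: set[int] = set()
    matched = 0
    for dist, i, j in pairs:
        if i in used_red or j in used_green:
            continue
        used_red.add(i)
        used_green.add(j)
        matched += 1
    return matched / len(red_segments)


def box_stats(values: np.ndarray) -> BoxStats:
    """Box-plot statistics with linear-interpolation quartiles.

    Whiskers extend at most 1.5 IQR beyond the quartiles but are clamped
    to the most extreme sample inside that range; samples beyond the
    whiskers are outliers.  The percentile rule (linear interpolation
    between order statistics) matters at small n and is therefore fixed
    here.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise DegenerateDataError("box_stats needs at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q75 - q25
    lo_lim, hi_lim = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    whisker_low = float(inside.min()) if inside.size else float(q25)
    whisker_high = float(inside.max()) if inside.size else float(q75)
    outliers = v[(v < whisker_low) | (v > whisker_high)].tolist()
    return BoxStats(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=whisker_low, whisker_high=whisker_high, outliers=outliers,
    )
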