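"""Cortical masking and pore/bone binarisation.

The cortical region of a section is the interior of the periosteal contour
minus the interiors of the endosteal contours.  Pixel membership uses a
half-open containment rule (left/top boundaries in, right/bottom boundaries
out) applied identically to both contour kinds, so abutting regions never
double-count a pixel.

Pore/bone thresholding uses the triangle (Zack) geometric construction on the
256-bin intensity histogram of the masked cortical pixels (configurable to
full-frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from canalmorph.image_io import ContourSet, Microradiograph

#: Sub-pixel offset implementing the half-open pixel-containment rule.
_HALF_OPEN_EPS = 2.0 ** -6


@dataclass
class CorticalMask:
    """Boolean cortical-bone mask with its area (Ct.Ar) and centre of mass.

    ``area_mm2`` is the true-pixel count times spacing² (μm² → mm²).
    ``centroid`` is the (x, y) mean pixel coordinate of the masked pixels.
    """

    mask: np.ndarray
    pixel_spacing_um: float
    area_mm2: float
    centroid: tuple[float, float]

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ThresholdResult:
    """A triangle-method threshold with the histogram it was derived from."""

    level: int
    histogram: np.ndarray
    side: str = "pores_below"  # or "pores_above"


def _contains_half_open(polygon, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Half-open point-in-polygon: strict interior test at centre + ε.

    Shifting the query point by +ε in x and y counts pixels on the left/top
    boundary as inside and pixels on the right/bottom boundary as outside,
    which makes adjacent regions partition the plane without double counting.
    """
    return shapely.contains_xy(polygon, xs + _HALF_OPEN_EPS, ys + _HALF_OPEN_EPS)


def cortical_mask(
    contours: ContourSet, shape: tuple[int, int], pixel_spacing_um: float
) -> CorticalMask:
    """Rasterise the cortex: inside the periosteal, outside every endosteal polygon.

    Raises if the periosteal polygon extends beyond the image bounds.
    """
    h, w = shape
    peri = contours.periosteal_polygon()
    minx, miny, maxx, maxy = peri.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise ValueError("periosteal polygon extends outside the image bounds")

    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.astype(float).ravel()
    ys = ys.astype(float).ravel()
    shapely.prepare(peri)
    inside = _contains_half_open(peri, xs, ys)
    for endo in contours.endosteal_polygons():
        shapely.prepare(endo)
        inside &= ~_contains_half_open(endo, xs, ys)
    mask = inside.reshape(h, w)

    n = int(mask.sum())
    if n == 0:
        raise ValueError("cortical mask is empty")
    area_mm2 = n * pixel_spacing_um**2 * 1e-6
    yy, xx = np.nonzero(mask)
    centroid = (float(xx.mean()), float(yy.mean()))
    return CorticalMask(mask=mask, pixel_spacing_um=pixel_spacing_um,
                        area_mm2=area_mm2, centroid=centroid)


def masked_histogram(
    micro: Microradiograph, cmask: CorticalMask | None = None
) -> np.ndarray:
    """256-bin intensity histogram of the masked (or full-frame) pixels."""
    if cmask is None:
        values = micro.pixels.ravel()
    else:
        values = micro.pixels[cmask.mask]
    return np.bincount(values, minlength=256)


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle-method (Zack) threshold on a 256-bin histogram.

    Geometric construction: normalise the bin axis and the count axis each to
    [0, 1]; draw the line from the histogram peak to the farthest nonzero bin
    on the longer-tail side; return the bin with maximum perpendicular
    distance to that line, ties broken toward the peak.  A histogram with a
    single nonzero bin returns that bin.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,) or (hist < 0).any():
        raise ValueError("histogram must be 256 non-negative counts")
    nonzero = np.nonzero(hist)[0]
    if nonzero.size == 0:
        raise ValueError("histogram is empty")
    if nonzero.size == 1:
        return int(nonzero[0])

    peak = int(np.argmax(hist))
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    # longer tail wins; on equal length the lighter (lower-mass) side is the tail
    left_len, right_len = peak - lo, hi - peak
    if left_len > right_len:
        ext = lo
    elif right_len > left_len:
        ext = hi
    else:
        left_mass = hist[lo:peak].sum()
        right_mass = hist[peak + 1 : hi + 1].sum()
        ext = lo if left_mass <= right_mass else hi
    if ext == peak:  # all mass at one end: no tail to cut
        return peak

    ymax = hist[peak]
    # normalised coordinates: x = bin/255, y = count/peak-count
    x1, y1 = peak / 255.0, 1.0
    x2, y2 = ext / 255.0, hist[ext] / ymax
    bins = np.arange(min(peak, ext), max(peak, ext) + 1)
    px = bins / 255.0
    py = hist[bins] / ymax
    # perpendicular distance of (px, py) from the peak-extreme line
    norm = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * px - (x2 - x1) * py + x2 * y1 - y2 * x1) / norm
    best = dist == dist.max()
    candidates = bins[best]
    # tie-break toward the peak
    return int(candidates[np.argmin(np.abs(candidates - peak))])


def threshold_section(
    micro: Microradiograph,
    cmask: CorticalMask | None = None,
    side: str = "pores_below",
    full_frame: bool = False,
) -> ThresholdResult:
    """Compute the triangle threshold for one section.

    By default the histogram is restricted to the cortical mask so that empty
    background does not dominate; ``full_frame=True`` uses the whole frame.
    """
    hist = masked_histogram(micro, None if full_frame else cmask)
    return ThresholdResult(level=triangle_threshold(hist), histogram=hist, side=side)


def binarize_pores(
    micro: Microradiograph,
    cmask: CorticalMask,
    level: int,
    side: str = "pores_below",
) -> np.ndarray:
    """Boolean pore-phase grid: masked pixels strictly beyond the threshold.

    ``side='pores_below'`` marks intensity < level as pore (radiolucent pores
    rendered dark); ``'pores_above'`` marks intensity > level.  Pixels outside
    the cortical mask are always False, so within the mask pore-phase and
    bone-phase counts partition the masked pixel count.
    """
    if not 0 <= level <= 255:
        raise ValueError("level must be in [0, 255]")
    if side == "pores_below":
        pores = micro.pixels < level
    elif side == "pores_above":
        pores = micro.pixels > level
    else:
        raise ValueError("side must be 'pores_below' or 'pores_above'")
    return pores & cmask.mask


def export_mask_tiff(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an inspectable 0/255 8-bit TIFF."""
    import tifffile

    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)),
                     photometric="minisblack")
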