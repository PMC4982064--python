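"""Low-level image operators for platelet morphometry.

Every stage of the segmentation workflow is exposed here as a pure function on
small, explicit data types: a calibrated single-channel raster (:class:`ImagePlane`),
a boolean mask (:class:`BinaryMask`, a plain boolean array), and a labelled
object map (:class:`LabelMap`).  The two classical auto-threshold selectors the
workflow relies on — the Kittler–Illingworth minimum-error criterion and Tsai's
moment-preserving rule — are implemented here directly on 256-bin histograms so
their behaviour is inspectable and testable bin by bin; the surrounding
morphology (rolling-ball background, Gaussian smoothing, hole filling,
distance-transform watershed, erosion, region measurement) delegates to
scipy.ndimage / scikit-image.

Conventions
-----------
* Histograms for thresholding use 256 equal-width bins spanning ``[min, max]``
  of the image, whatever the input dtype, so float images are well defined.
* Pixels strictly greater than a returned threshold are foreground
  (bright structures on a dark background, as in fluorescence).
* Foreground objects are 8-connected; hole filling treats background as
  4-connected (the standard duality).
* Erosion uses a 3x3 cross structuring element per iteration.
* Perimeters use scikit-image's weighted boundary-step estimator
  (``regionprops.perimeter``); circularity tolerances elsewhere are calibrated
  to that estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as _morph
from skimage import restoration as _restoration
from skimage import segmentation as _skseg
from skimage.measure import regionprops

logger = logging.getLogger("plateletquant")

#: number of histogram bins used by both auto-threshold selectors
N_BINS = 256

#: variance floor (bin^2 units) for the minimum-error criterion: the
#: quantization variance of a single histogram bin.  Keeps single-bin classes
#: well defined (e.g. a two-valued image).
_VAR_FLOOR = 1.0 / 12.0


class ParameterError(ValueError):
    """An operator was called with an out-of-range parameter."""


class DegenerateImageError(ValueError):
    """The image histogram cannot support the requested operation
    (e.g. thresholding a constant image)."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

# A BinaryMask is a plain 2D boolean ndarray with the same shape/calibration
# as the ImagePlane it came from.
BinaryMask = np.ndarray


@dataclass(frozen=True)
class ImagePlane:
    """A calibrated 2D single-channel intensity raster.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (stored as float64).
    pixel_size_nm
        Physical edge length of one pixel in nanometres (> 0).
    """

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("ImagePlane requires a 2D raster")
        if not np.all(np.isfinite(px)):
            raise ParameterError("ImagePlane intensities must be finite")
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "ImagePlane":
        """Same calibration, new pixel data."""
        return ImagePlane(pixels=pixels, pixel_size_nm=self.pixel_size_nm)


@dataclass(frozen=True)
class LabelMap:
    """Connected-object labelling: 0 = background, 1..n_objects = objects."""

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ParameterError("LabelMap requires a 2D raster")
        if lab.size and lab.max(initial=0) > self.n_objects:
            raise ParameterError("label values exceed n_objects")
        object.__setattr__(self, "labels", lab.astype(np.int32, copy=False))


@dataclass(frozen=True)
class RegionMetrics:
    """Shape morphometrics of one labelled region.

    ``circularity = 4*pi*area/perimeter**2`` is dimensionless, 1 for a perfect
    circle; discretization can push it slightly above 1.  Regions whose
    estimated perimeter is zero (single pixels) get circularity 0.
    """

    label: int
    area_um2: float
    perimeter_um: float
    circularity: float
    centroid_px: tuple[float, float]
    equivalent_radius_um: float


# ---------------------------------------------------------------------------
# background and smoothing
# ---------------------------------------------------------------------------


def rolling_ball_subtract(img: ImagePlane, radius_px: int) -> ImagePlane:
    """Subtract an uneven background estimated by the rolling-ball construction.

    The background is the surface traced by the top of a ball of the given
    radius rolled beneath the intensity landscape (a grey-scale opening with a
    ball-shaped kernel); structures much smaller than the ball are preserved.
    Output is clamped at zero and never exceeds the input.
    """
    if int(radius_px) < 1:
        raise ParameterError("rolling-ball radius must be >= 1 pixel")
    background = _restoration.rolling_ball(img.pixels, radius=int(radius_px))
    out = np.clip(img.pixels - background, 0.0, None)
    return img.with_pixels(out)


def gaussian_blur(img: ImagePlane, sigma_px: float) -> ImagePlane:
    """Isotropic Gaussian smoothing; ``sigma_px = 0`` is the identity.

    Boundary handling is 'nearest' (edge replication), which conserves the
    total intensity of interior structures.
    """
    if sigma_px < 0:
        raise ParameterError("sigma must be non-negative")
    if sigma_px == 0:
        return img.with_pixels(img.pixels.copy())
    out = ndi.gaussian_filter(img.pixels, sigma=float(sigma_px), mode="nearest")
    return img.with_pixels(out)


# ---------------------------------------------------------------------------
# histogram thresholding
# ---------------------------------------------------------------------------


def _histogram(img: ImagePlane) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram over [min, max]; raises on constant images."""
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if not hi > lo:
        raise DegenerateImageError("constant image has no separable histogram")
    hist, edges = np.histogram(img.pixels, bins=N_BINS, range=(lo, hi))
    return hist.astype(np.float64), edges


def kittler_illingworth_bin(hist: np.ndarray) -> int:
    """Bin index minimizing the Kittler–Illingworth minimum-error criterion.

    Splitting at bin ``t`` puts bins ``0..t`` in the dark class and
    ``t+1..end`` in the bright class; the criterion is

        J(t) = 1 + 2[P1 ln s1 + P2 ln s2] - 2[P1 ln P1 + P2 ln P2]

    with class priors P and standard deviations s computed from the histogram
    (variances floored at one-twelfth of a bin).  On well-separated histograms
    J is flat across the empty gap between the classes, so the returned bin is
    the middle of the minimal plateau (the contiguous run of bins within 1e-12
    of the minimum) — a mid-gap threshold.
    """
    h = np.asarray(hist, dtype=np.float64)
    if h.sum() <= 0 or np.count_nonzero(h) < 2:
        raise DegenerateImageError("histogram needs at least two occupied bins")
    p = h / h.sum()
    i = np.arange(h.size, dtype=np.float64)

    P1 = np.cumsum(p)
    m1 = np.cumsum(p * i)
    s1 = np.cumsum(p * i * i)
    P2 = 1.0 - P1
    m2 = m1[-1] - m1
    s2 = s1[-1] - s1

    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = m1 / P1
        mu2 = m2 / P2
        var1 = np.maximum(s1 / P1 - mu1 * mu1, _VAR_FLOOR)
        var2 = np.maximum(s2 / P2 - mu2 * mu2, _VAR_FLOOR)
        J = 1.0 + P1 * np.log(var1) + P2 * np.log(var2) \
            - 2.0 * (P1 * np.log(P1) + P2 * np.log(P2))

    J = J[:-1]  # splitting after the last bin leaves one class empty
    valid = (P1[:-1] > 0) & (P2[:-1] > 0)
    J = np.where(valid, J, np.inf)
    if not np.isfinite(J).any():
        raise DegenerateImageError("no valid split point in histogram")
    return plateau_argmin(J)


def plateau_argmin(J: np.ndarray, tol: float = 1e-12) -> int:
    """Middle index of the contiguous minimal plateau of a criterion curve."""
    t = int(np.argmin(J))
    jmin = J[t]
    lo = t
    while lo > 0 and J[lo - 1] <= jmin + tol:
        lo -= 1
    hi = t
    while hi < J.size - 1 and J[hi + 1] <= jmin + tol:
        hi += 1
    return (lo + hi) // 2


def tsai_moment_bin(hist: np.ndarray) -> int:
    """Bin index of Tsai's moment-preserving threshold.

    Solves for the two representative grey levels z0 < z1 and dark-class
    fraction p0 that preserve the first three histogram moments, then returns
    the bin where the cumulative histogram is closest to p0 (ties to the
    lowest bin; clamped so both classes are non-empty).
    """
    h = np.asarray(hist, dtype=np.float64)
    if h.sum() <= 0 or np.count_nonzero(h) < 2:
        raise DegenerateImageError("histogram needs at least two occupied bins")
    p = h / h.sum()
    z = np.arange(h.size, dtype=np.float64)
    m1 = float(np.sum(p * z))
    m2 = float(np.sum(p * z * z))
    m3 = float(np.sum(p * z * z * z))

    cd = m2 - m1 * m1
    if cd <= 1e-12:
        raise DegenerateImageError("zero-variance histogram")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise DegenerateImageError("moment equations have no real roots")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 <= z0:
        raise DegenerateImageError("moment equations degenerate")
    p0 = (z1 - m1) / (z1 - z0)

    cum = np.cumsum(p)
    t = int(np.argmin(np.abs(cum - p0)))
    return min(t, h.size - 2)


def min_error_threshold(img: ImagePlane) -> float:
    """Kittler–Illingworth minimum-error threshold as a grey level.

    Pixels strictly greater than the returned value are foreground.
    """
    hist, edges = _histogram(img)
    t = kittler_illingworth_bin(hist)
    return float(edges[t + 1])


def moment_threshold(img: ImagePlane) -> float:
    """Tsai moment-preserving threshold as a grey level.

    Pixels strictly greater than the returned value are foreground.  Because
    bins span ``[min, max]`` of the image, the selected pixel partition is
    covariant under an additive intensity offset.
    """
    hist, edges = _histogram(img)
    t = tsai_moment_bin(hist)
    return float(edges[t + 1])


# ---------------------------------------------------------------------------
# binary morphology
# ---------------------------------------------------------------------------

_CROSS = ndi.generate_binary_structure(2, 1)
_SQUARE = ndi.generate_binary_structure(2, 2)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background regions not 4-connected to the raster border."""
    return ndi.binary_fill_holes(mask, structure=_CROSS)


def erode(mask: BinaryMask, n_px: int) -> BinaryMask:
    """``n_px`` iterations of binary erosion with a 3x3 cross element."""
    if n_px < 0:
        raise ParameterError("erosion count must be non-negative")
    if n_px == 0:
        return mask.copy()
    return ndi.binary_erosion(mask, structure=_CROSS, iterations=int(n_px))


def label_components(mask: BinaryMask, connectivity: int = 8) -> LabelMap:
    """Connected-component labelling under 4- or 8-connectivity."""
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    structure = _SQUARE if connectivity == 8 else _CROSS
    labels, n = ndi.label(mask, structure=structure)
    return LabelMap(labels=labels, n_objects=int(n))


def watershed_split(mask: BinaryMask, h: float = 1.0) -> LabelMap:
    """Separate touching objects with a distance-transform watershed.

    The negated Euclidean distance transform of the mask is flooded from its
    regional maxima; maxima shallower than ``h`` (pixels) are suppressed so
    small boundary ripples do not over-segment.  Every foreground pixel ends
    up in exactly one label and no label leaks outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return LabelMap(labels=np.zeros(mask.shape, dtype=np.int32), n_objects=0)
    dist = ndi.distance_transform_edt(mask)
    peaks = _morph.h_maxima(dist, h)
    markers, n = ndi.label(peaks, structure=_SQUARE)
    if n == 0:
        # h swallowed every maximum: fall back to one marker per component
        return label_components(mask, connectivity=8)
    labels = _skseg.watershed(-dist, markers=markers, mask=mask)
    return LabelMap(labels=labels, n_objects=int(n))


# ---------------------------------------------------------------------------
# region measurement
# ---------------------------------------------------------------------------


def measure_regions(labels: LabelMap, pixel_size_nm: float) -> list[RegionMetrics]:
    """Area (um^2), perimeter (um), circularity and centroid per label."""
    if not pixel_size_nm > 0:
        raise ParameterError("pixel_size_nm must be positive")
    if labels.n_objects == 0:
        return []
    scale_um = pixel_size_nm / 1000.0
    out: list[RegionMetrics] = []
    for rp in regionprops(labels.labels):
        area_px = float(rp.area)
        perim_px = float(rp.perimeter)
        area_um2 = area_px * scale_um * scale_um
        if perim_px > 0:
            circ = 4.0 * np.pi * area_px / (perim_px * perim_px)
        else:
            circ = 0.0
        out.append(
            RegionMetrics(
                label=int(rp.label),
                area_um2=area_um2,
                perimeter_um=perim_px * scale_um,
                circularity=float(circ),
                centroid_px=(float(rp.centroid[0]), float(rp.centroid[1])),
                equivalent_radius_um=float(np.sqrt(area_um2 / np.pi)),
            )
        )
    return out
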