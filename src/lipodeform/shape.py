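"""Per-frame liposome segmentation and shape-distortion metrics.

A liposome cross-section is segmented from a grayscale fluorescence frame by
global Otsu thresholding (holes filled, debris removed), and its shape is
summarized by three dimensionless measures used throughout the pipeline:

* aspect ratio  AR = L_l / L_s, the longest over the shortest (caliper/
  Feret) diameter of the contour; 1 for a circle;
* area ratio    dA = A_t / A_ave, apparent cross-sectional area relative to
  the pre-addition baseline;
* normalized radius  R_nor(theta) = R(theta) / R_ave, the angle-resolved
  radius from the centroid over its mean; its deviation from 1 quantifies
  contour distortion (reported as the RMS "amplitude").

Deformation is flagged when AR or dA strictly exceeds 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.filters import threshold_otsu
from skimage.measure import find_contours

AR_THRESHOLD = 1.1
DELTA_A_THRESHOLD = 1.1
MIN_AREA_PX = 50

__all__ = [
    "SegmentedObject",
    "ContourProfile",
    "ShapeMetrics",
    "segment_all",
    "segment_frame",
    "aspect_ratio",
    "feret_diameters",
    "radial_profile",
    "normalized_radius",
    "distortion_amplitude",
    "delta_area",
    "classify_deformation",
    "compute_metrics",
]


@dataclass
class SegmentedObject:
    """One connected foreground component: mask, centroid (row, col),
    pixel area and ordered sub-pixel boundary."""

    mask: np.ndarray
    centroid: tuple
    area_px: int
    contour: np.ndarray   # (n, 2) ordered (row, col) points


@dataclass
class ContourProfile:
    """Radius from the centroid sampled on a regular angle grid."""

    theta: np.ndarray
    radius: np.ndarray

    @property
    def r_ave(self):
        return float(np.mean(self.radius))


@dataclass
class ShapeMetrics:
    area_px: float
    ar: float
    delta_a: float        # NaN when no baseline is available
    amplitude: float
    r_nor: np.ndarray
    deformed_by_ar: bool
    deformed_by_da: bool


# ----------------------------------------------------------------------------
# Segmentation
# ----------------------------------------------------------------------------

def _smooth_contour(contour, window=11):
    """Periodic moving average along the contour; suppresses the ~0.5 px
    pixelation ripple of a rasterized boundary without eroding contour
    features much larger than the window."""
    n = len(contour)
    if n <= window:
        return contour
    kernel = np.ones(window) / window
    out = np.empty_like(contour)
    for j in range(2):
        padded = np.concatenate([contour[-window:, j], contour[:, j],
                                 contour[:window, j]])
        out[:, j] = np.convolve(padded, kernel, mode="same")[window:window + n]
    return out


def _object_from_component(mask, smooth_window=11):
    centroid = ndimage.center_of_mass(mask)
    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    # drop the duplicated closing point before periodic smoothing
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    return SegmentedObject(mask=mask, centroid=tuple(centroid),
                           area_px=int(mask.sum()),
                           contour=_smooth_contour(contour, smooth_window))


def segment_all(image, min_area_px=MIN_AREA_PX, min_contrast_snr=6.0):
    """All foreground components of a frame after global Otsu thresholding.

    The threshold is computed per frame (robust to focus and bleaching
    drift); holes are filled so a bright membrane ring yields the full
    cross-sectional disk; components below ``min_area_px`` (debris, noise
    speckle) are discarded.  On a background-only frame Otsu would split
    the noise distribution in half, so a frame is called empty unless the
    foreground/background mean separation exceeds ``min_contrast_snr``
    times the robust (MAD) noise level.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if image.max() == image.min():
        return []
    thr = threshold_otsu(image)
    fg = image > thr
    sigma = 1.4826 * np.median(np.abs(image - np.median(image)))
    if sigma > 0 and fg.any() and (~fg).any():
        if image[fg].mean() - image[~fg].mean() < min_contrast_snr * sigma:
            return []
    binary = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(binary)
    objects = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < min_area_px:
            continue
        objects.append(_object_from_component(mask))
    return objects


def segment_frame(image, prior_centroid=None, min_area_px=MIN_AREA_PX):
    """Segment one liposome from a frame.

    Among the Otsu foreground components, returns the one nearest
    ``prior_centroid`` (for time-lapse tracking) or the largest when no
    prior is given; ``None`` when nothing of at least ``min_area_px``
    survives (feeds rupture detection).
    """
    objects = segment_all(image, min_area_px=min_area_px)
    if not objects:
        return None
    if prior_centroid is None:
        return max(objects, key=lambda o: o.area_px)
    prior = np.asarray(prior_centroid, dtype=float)
    return min(objects,
               key=lambda o: float(np.hypot(*(np.asarray(o.centroid) - prior))))


# ----------------------------------------------------------------------------
# Aspect ratio (caliper diameters)
# ----------------------------------------------------------------------------

def feret_diameters(points):
    """(min, max) caliper diameters of a point set.

    The maximum Feret diameter is the largest pairwise distance between
    convex-hull vertices; the minimum is the smallest hull width over the
    edge-normal directions (rotating calipers).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points for caliper diameters")
    try:
        hull = ConvexHull(points)
    except Exception as exc:   # qhull degenerate input
        raise ValueError(f"degenerate contour: {exc}") from exc
    verts = points[hull.vertices]
    diffs = verts[:, None, :] - verts[None, :, :]
    feret_max = float(np.sqrt((diffs ** 2).sum(-1)).max())
    widths = []
    n = len(verts)
    for i in range(n):
        edge = verts[(i + 1) % n] - verts[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        proj = verts @ normal
        widths.append(proj.max() - proj.min())
    feret_min = float(min(widths))
    return feret_min, feret_max


def aspect_ratio(obj):
    """AR = longest / shortest caliper diameter of the contour (>= 1)."""
    contour = obj.contour if isinstance(obj, SegmentedObject) else obj
    feret_min, feret_max = feret_diameters(contour)
    if feret_min <= 0:
        raise ValueError("degenerate contour with zero width")
    return feret_max / feret_min


# ----------------------------------------------------------------------------
# Radial profile and distortion
# ----------------------------------------------------------------------------

def radial_profile(obj, n_angles=360):
    """Radius from the mask centroid sampled at ``n_angles`` regular angles.

    Contour vertices are converted to polar coordinates about the centroid
    and the radius is linearly interpolated (with 2*pi wraparound) onto the
    regular grid — 1-degree steps by default.  The contour is assumed
    star-convex about the centroid; where several vertices share an angle
    the interpolation follows the outermost ordering of the sorted samples.
    """
    contour = obj.contour if isinstance(obj, SegmentedObject) else np.asarray(obj)
    cy, cx = (obj.centroid if isinstance(obj, SegmentedObject)
              else contour.mean(axis=0))
    dy = contour[:, 0] - cy
    dx = contour[:, 1] - cx
    phi = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    r = np.hypot(dy, dx)
    order = np.lexsort((r, phi))
    phi, r = phi[order], r[order]
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    radius = np.interp(theta, phi, r, period=2 * np.pi)
    if np.any(radius <= 0):
        raise ValueError("non-positive radius in contour profile")
    return ContourProfile(theta=theta, radius=radius)


def normalized_radius(profile):
    """R_nor(theta) = R(theta) / R_ave; the mean over the grid is 1."""
    r_ave = profile.r_ave
    if r_ave <= 0:
        raise ValueError("non-positive mean radius")
    return profile.radius / r_ave


def distortion_amplitude(r_nor, method="rms"):
    """Scalar contour-distortion amplitude: deviation of R_nor from 1.

    ``rms`` (default) is the root-mean-square deviation; ``std`` and ``max``
    are alternate summaries (standard deviation of R_nor; largest absolute
    deviation).
    """
    dev = np.asarray(r_nor, dtype=float) - 1.0
    if method == "rms":
        return float(np.sqrt(np.mean(dev ** 2)))
    if method == "std":
        return float(np.std(dev))
    if method == "max":
        return float(np.max(np.abs(dev)))
    raise ValueError(f"unknown amplitude method {method!r}")


def delta_area(a_t, a_ave):
    """dA = A_t / A_ave relative to the pre-addition baseline area."""
    if a_ave <= 0:
        raise ValueError("baseline area must be positive")
    return a_t / a_ave


def classify_deformation(ar, da, ar_threshold=AR_THRESHOLD,
                         da_threshold=DELTA_A_THRESHOLD):
    """Strict-inequality deformation flags: (AR > 1.1, dA > 1.1)."""
    return bool(ar > ar_threshold), bool(da > da_threshold)


def compute_metrics(obj, a_ave=None, n_angles=360, amplitude_method="rms",
                    ar_threshold=AR_THRESHOLD, da_threshold=DELTA_A_THRESHOLD):
    """All shape metrics of one segmented liposome.

    ``a_ave`` is the track's pre-addition baseline area; when absent, dA is
    NaN and the dA flag false.
    """
    ar = aspect_ratio(obj)
    profile = radial_profile(obj, n_angles=n_angles)
    r_nor = normalized_radius(profile)
    amplitude = distortion_amplitude(r_nor, method=amplitude_method)
    if a_ave is not None:
        da = delta_area(obj.area_px, a_ave)
    else:
        da = np.nan
    flag_ar, flag_da = classify_deformation(ar, da if np.isfinite(da) else 0.0,
                                            ar_threshold, da_threshold)
    return ShapeMetrics(area_px=float(obj.area_px), ar=ar, delta_a=da,
                        amplitude=amplitude, r_nor=r_nor,
                        deformed_by_ar=flag_ar, deformed_by_da=flag_da)
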