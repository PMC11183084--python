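"""Image extraction: from bottom/side views to width series and trajectories.

Conventions (used consistently everywhere):

* pixel coordinates are 0-based with the origin at the top-left corner,
  x (column index) rightward, y (row index) downward;
* in side views gravity points along +y, so a sagging strut has a
  positive pitch angle without any axis flip;
* every pixel-to-mm conversion flows through a single calibration value,
  set from the known outer diameter of the nozzle visible at the top of
  the frame (0.82 mm for a 21G needle, to about two pixels).

Extraction is deterministic: no RNG is involved anywhere in this module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree
from skimage.feature import canny
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.measure import label
from skimage.morphology import closing as _closing, disk, remove_small_holes

from .optics import OpticalConfig, PatternObservation
from .spreading import SpreadingSeries
from .trajectory import StrutTrajectory

__all__ = [
    "FrameSeries",
    "ContourPair",
    "CalibrationError",
    "ContourExtractionError",
    "OrientationError",
    "to_grayscale",
    "calibrate_scale",
    "extract_contours",
    "contour_mask",
    "in_gel_strut_mask",
    "centerline_and_diameter",
    "width_series_from_snapshot",
    "stripe_angle",
    "stripe_angle_in_strut",
    "side_view_to_trajectory",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Nozzle not detected; a manual scale must be supplied."""


class ContourExtractionError(ValueError):
    """Could not find the two strut contours."""


class OrientationError(ValueError):
    """No dominant stripe orientation in the region of interest."""


@dataclass(frozen=True)
class FrameSeries:
    """A time-stamped sequence of grayscale frames with one pixel scale."""

    frames: tuple
    timestamps: np.ndarray
    scale: float  # mm per pixel

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be nondecreasing")
        if not (self.scale > 0):
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class ContourPair:
    """Upper and lower strut contours as ordered (x, y) pixel polylines."""

    upper: np.ndarray  # (N, 2), x-monotone
    lower: np.ndarray

    def __post_init__(self) -> None:
        for name in ("upper", "lower"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
                raise ValueError(f"{name} must be an (N>=2, 2) polyline")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name} must be x-monotone")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Float grayscale in [0, 1]; RGB is converted by luminance."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    img = img.astype(np.float64)
    if img.max() > 1.0:
        img = img / (65535.0 if img.max() > 255 else 255.0)
    return img


def calibrate_scale(
    image: np.ndarray, nozzle_od_mm: float = 0.82, top_rows: int = 12
) -> float:
    """mm-per-pixel scale from the nozzle width at the top of the frame.

    The nozzle is located as the darkest contiguous vertical structure
    within the first ``top_rows`` rows; its width in pixels divided into
    the known outer diameter gives the scale (accuracy ~2 px).
    """
    img = to_grayscale(image)
    band = img[:top_rows]
    profile = band.mean(axis=0)
    lo, hi = profile.min(), profile.max()
    if hi - lo < 0.2:
        raise CalibrationError("no nozzle found in the top rows (flat intensity)")
    dark = profile < lo + 0.3 * (hi - lo)
    # longest contiguous dark run
    best_len, best_start, run_start = 0, -1, None
    for i, flag in enumerate(np.append(dark, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < 3:
        raise CalibrationError("no nozzle found in the top rows")
    return nozzle_od_mm / best_len


def _canny_edges(
    img: np.ndarray, sigma: float, low_frac: float, high_frac: float
) -> np.ndarray:
    """Canny edges with hysteresis thresholds as fractions of the Otsu
    level of the smoothed gradient magnitude."""
    gm = sobel(gaussian(img, sigma=sigma))
    if gm.max() <= 0:
        raise ContourExtractionError("blank image: no gradients")
    level = threshold_otsu(gm)
    return canny(
        img, sigma=sigma, low_threshold=low_frac * level, high_threshold=high_frac * level
    )


def extract_contours(
    image: np.ndarray,
    sigma: float = 2.0,
    low_frac: float = 0.5,
    high_frac: float = 1.0,
    roi: tuple[slice, slice] | None = None,
    min_columns: int = 10,
) -> ContourPair:
    """Upper and lower strut contours from a side-view (or in-gel) image.

    Canny edges are reduced per column to their extreme rows over the
    longest contiguous column run, yielding two x-monotone chains.
    ``roi`` restricts the search (e.g. to exclude the nozzle).
    """
    img = to_grayscale(image)
    row0 = col0 = 0
    if roi is not None:
        row0 = roi[0].start or 0
        col0 = roi[1].start or 0
        img = img[roi]
    edges = _canny_edges(img, sigma, low_frac, high_frac)

    cols_with = np.nonzero(edges.any(axis=0))[0]
    if len(cols_with) < min_columns:
        raise ContourExtractionError("fewer than two usable edge chains found")
    # longest contiguous run of columns holding >= 2 edge pixels
    counts = edges.sum(axis=0)
    ok = counts >= 2
    best_len, best_start, run_start = 0, -1, None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < min_columns:
        raise ContourExtractionError("no contiguous strut section found")

    cols = np.arange(best_start, best_start + best_len)
    upper = np.empty((best_len, 2))
    lower = np.empty((best_len, 2))
    for k, c in enumerate(cols):
        rows = np.nonzero(edges[:, c])[0]
        upper[k] = (c + col0, rows.min() + row0)
        lower[k] = (c + col0, rows.max() + row0)
    if np.any(upper[:, 1] >= lower[:, 1]):
        raise ContourExtractionError("contours cross or coincide")
    return ContourPair(upper=upper, lower=lower)


def contour_mask(contours: ContourPair, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the region enclosed between the two contours."""
    mask = np.zeros(shape, dtype=bool)
    for (x, yu), (_, yl) in zip(contours.upper, contours.lower):
        c = int(round(x))
        if 0 <= c < shape[1]:
            mask[int(math.ceil(yu)): int(math.floor(yl)) + 1, c] = True
    return mask


def in_gel_strut_mask(
    image: np.ndarray,
    border_frac: float = 0.12,
    residual_frac: float = 0.1,
    close_radius: int = 8,
) -> np.ndarray:
    """Mask of an in-gel strut visible only through stripe displacement.

    With no intensity step at the strut boundary, the strut is found by
    reference-wave demodulation: the undisturbed stripe pattern is
    fitted as a plane wave on the top image border and subtracted
    everywhere; inside the strut the refraction displaces the stripes,
    so the squared residual is large (it jumps within a pixel of the
    contact line, keeping the boundary sharp).  The residual oscillates,
    so the thresholded mask is morphologically closed — which cannot
    move its outer boundary — then reduced to its largest connected
    component with holes filled (the displacement vanishes along the
    strut centerline, leaving an enclosed low-residual lane).
    """
    img = to_grayscale(image)
    b = max(6, int(border_frac * img.shape[0]))
    top = img[:b]

    c, A, kx, ky, phi = _plane_wave_fit(top)
    Y, X = np.mgrid[0: img.shape[0], 0: img.shape[1]].astype(float)
    pred = c + A * np.sin(kx * X + ky * Y + phi)
    res2 = (img - pred) ** 2

    mask = res2 > residual_frac * A**2
    mask = _closing(mask, disk(3))
    # bridge the across-strut low-residual lane with a vertical element
    # (the strut is a horizontal band; closing cannot move the outer rim)
    mask = _closing(mask, np.ones((2 * close_radius + 1, 3), dtype=bool))
    lab = label(mask)
    if lab.max() == 0:
        raise ContourExtractionError("no displaced-stripe region found")
    sizes = np.bincount(lab.ravel())[1:]
    mask = lab == (1 + int(np.argmax(sizes)))
    return remove_small_holes(mask, max_size=int(mask.sum()))


def centerline_and_diameter(
    contours: ContourPair,
    scale: float,
    smooth_window: int = 11,
) -> StrutTrajectory:
    """Centerline, pitch angle and local diameter from a contour pair.

    Both contours are resampled at 1-px abscissa spacing and averaged
    pointwise to the centerline; the local diameter at each centerline
    point is the nearest-neighbor distance to the upper contour plus the
    nearest-neighbor distance to the lower one; the tangent angle comes
    from a Savitzky-Golay local quadratic over ``smooth_window`` points.
    """
    x0 = max(contours.upper[0, 0], contours.lower[0, 0])
    x1 = min(contours.upper[-1, 0], contours.lower[-1, 0])
    xs = np.arange(math.ceil(x0), math.floor(x1) + 1, dtype=float)
    if len(xs) < 8:
        raise ContourExtractionError("contour overlap too short")
    yu = np.interp(xs, contours.upper[:, 0], contours.upper[:, 1])
    yl = np.interp(xs, contours.lower[:, 0], contours.lower[:, 1])
    if np.any(yu >= yl):
        raise ContourExtractionError("contours cross after resampling")
    yc = 0.5 * (yu + yl)

    # single-pixel quantization of the edge rows is removed by a local
    # quadratic; the smoothed centerline is used consistently for the
    # tangent angle, the arc length and the diameter query points, so
    # cos(alpha) = dx/ds holds on the output
    win = min(smooth_window, len(xs) if len(xs) % 2 else len(xs) - 1)
    ysm = savgol_filter(yc, window_length=win, polyorder=2)
    dy = np.gradient(ysm)  # same central stencil as the arc-length step
    alpha = np.arctan(dy)  # y down == gravity down in side view

    ds = np.hypot(np.diff(xs), np.diff(ysm))
    s = np.concatenate([[0.0], np.cumsum(ds)]) * scale

    tree_u = cKDTree(contours.upper)
    tree_l = cKDTree(contours.lower)
    pts = np.column_stack([xs, ysm])
    d = (tree_u.query(pts)[0] + tree_l.query(pts)[0]) * scale

    # x is kept absolute (mm in the image frame) so extracted trajectories
    # can be registered against renders or other frames
    return StrutTrajectory(s=s, x=xs * scale, alpha=alpha, d=d)


def _polyline_stations(
    path: np.ndarray, step: float, corner_margin: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Station positions, tangents and arc lengths along a polyline path."""
    path = np.asarray(path, dtype=float)
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    corners = cum[1:-1]  # arc lengths of interior vertices

    stations, tangents, arcs = [], [], []
    ell = step / 2.0
    while ell < total:
        if len(corners) == 0 or np.min(np.abs(corners - ell)) > corner_margin:
            i = int(np.searchsorted(cum, ell, side="right") - 1)
            i = min(i, len(seg) - 1)
            frac = (ell - cum[i]) / seg_len[i]
            stations.append(path[i] + frac * seg[i])
            tangents.append(seg[i] / seg_len[i])
            arcs.append(ell)
        else:
            log.info("station at arc length %.2f mm falls on a corner; skipped", ell)
        ell += step
    return np.array(stations), np.array(tangents), np.array(arcs), total


def width_series_from_snapshot(
    image: np.ndarray,
    path_mm: np.ndarray,
    v_p: float,
    scale: float,
    station_step: float = 2.0,
    corner_margin: float = 1.0,
    avg_half_px: int = 3,
    max_half_width: float = 1.2,
    edge_max_level: float = 0.25,
) -> SpreadingSeries:
    """Strut width versus elapsed time from one end-of-print snapshot.

    ``path_mm`` is the printed path as an (N, 2) polyline in mm image
    coordinates, ordered from the print start (the oldest material) to
    the nozzle position; the age of the material at a station is the
    remaining path length to the nozzle divided by the print speed.

    At stations spaced ``station_step`` along the path (corners
    excluded), the width is measured perpendicular to the local path
    direction by locating the two dark contact-line minima either side
    of the path, with parabolic sub-pixel refinement, averaged over
    +/- ``avg_half_px`` pixels along the path.  Stations without a
    detectable pair of edge dips (e.g. beyond the deposited strand) are
    skipped with a log entry.
    """
    img = to_grayscale(image)
    stations, tangents, arcs, total = _polyline_stations(
        np.asarray(path_mm, float), station_step, corner_margin
    )
    if len(stations) == 0:
        raise ValueError("no stations on the path (corner-only or too short)")

    half_px = int(round(max_half_width / scale))
    offs = np.arange(-half_px, half_px + 0.25, 0.5)  # px, across-path
    t_list, a_list = [], []
    for p, u, ell in zip(stations, tangents, arcs):
        nvec = np.array([-u[1], u[0]])
        prof = np.zeros(len(offs))
        for k in range(-avg_half_px, avg_half_px + 1):
            pts = (p + k * scale * u)[None, :] + offs[:, None] * scale * nvec[None, :]
            rows = pts[:, 1] / scale
            cols = pts[:, 0] / scale
            prof += map_coordinates(img, [rows, cols], order=3, mode="nearest")
        prof /= 2 * avg_half_px + 1

        mid = len(offs) // 2
        left = prof[: mid - 2]
        right = prof[mid + 3:]
        if len(left) < 3 or len(right) < 3:
            continue
        iL = int(np.argmin(left))
        iR = int(np.argmin(right)) + mid + 3
        # the contact-line darkening is near-black, well below the darkest
        # background stripe, so an absolute level separates the two
        if prof[iL] > edge_max_level or prof[iR] > edge_max_level:
            log.info("station at %.2f mm: no edge dips; skipped", ell)
            continue
        oL = offs[iL] + _parabolic_offset(prof, iL) * 0.5
        oR = offs[iR] + _parabolic_offset(prof, iR) * 0.5
        a_list.append((oR - oL) * scale)
        t_list.append((total - ell) / v_p)

    if len(t_list) < 3:
        raise ValueError("fewer than 3 stations with measurable width")
    order = np.argsort(t_list)
    return SpreadingSeries(t=np.asarray(t_list)[order], a=np.asarray(a_list)[order])


def _parabolic_offset(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of an extremum by a 3-point parabola (in samples)."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if abs(denom) < 1e-12:
        return 0.0
    return 0.5 * (y[i - 1] - y[i + 1]) / denom


def _plane_wave_fit(patch: np.ndarray) -> tuple[float, float, float, float, float]:
    """Fit c + A sin(kx x + ky y + phi) to a striped patch.

    Initialization: the zero-padded FFT peak (equivalently the dominant
    structure-tensor orientation plus the projected frequency);
    refinement: nonlinear least squares of the plane-wave model, which
    removes the O(k^2) orientation bias of discrete-gradient estimators.
    Returns (c, A, kx, ky, phi) with k in rad/px in patch coordinates.
    """
    p = patch - patch.mean()
    if p.std() < 0.02:
        raise OrientationError("no dominant orientation (flat patch)")
    ny, nx = p.shape
    pad = 4
    F = np.fft.rfft2(p * np.hanning(ny)[:, None] * np.hanning(nx)[None, :],
                     s=(pad * ny, pad * nx))
    mag = np.abs(F)
    mag[0, 0] = 0.0
    iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
    ky0 = iy / (pad * ny)
    if ky0 > 0.5:
        ky0 -= 1.0
    kx0 = ix / (pad * nx)
    kx0 *= 2 * math.pi
    ky0 *= 2 * math.pi  # rad per px

    Y, X = np.mgrid[0:ny, 0:nx].astype(float)

    def resid(q):
        c, A, kx, ky, phi = q
        return (c + A * np.sin(kx * X + ky * Y + phi) - patch).ravel()

    A0 = patch.std() * math.sqrt(2.0)
    best = None
    for phi0 in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2):
        res = least_squares(resid, x0=[patch.mean(), A0, kx0, ky0, phi0],
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    c, A, kx, ky, phi = best.x
    if abs(A) < 0.05:
        raise OrientationError("no dominant orientation (amplitude below noise)")
    if A < 0:
        A, phi = -A, phi + math.pi
    return float(c), float(A), float(kx), float(ky), float(phi)


def _plane_wave_angle(patch: np.ndarray) -> float:
    """Dominant stripe angle (deg vs x axis) of a sinusoidal patch."""
    _, _, kx, ky, _ = _plane_wave_fit(patch)
    # stripes are the level sets of kx x + ky y: angle vs x axis
    ang = math.degrees(math.atan2(abs(kx), abs(ky)))
    if not (0.0 < ang < 90.0):
        raise OrientationError(f"degenerate stripe angle {ang:.2f} deg")
    return ang


def stripe_angle(image: np.ndarray, roi: tuple[slice, slice]) -> float:
    """Dominant stripe angle (degrees vs the x axis) within a ROI."""
    return _plane_wave_angle(to_grayscale(image)[roi])


def stripe_angle_in_strut(
    image: np.ndarray,
    strut_roi: tuple[slice, slice],
    reference_roi: tuple[slice, slice],
    config: OpticalConfig | None = None,
) -> PatternObservation:
    """Apparent stripe angle inside the strut and the implied magnification.

    The reference angle is measured outside the strut; if ``config`` is
    given, its ``pattern_angle_deg`` is used as the true angle instead
    of the measured reference (the reference is still required and
    sanity-checks the pattern).
    """
    img = to_grayscale(image)
    inner = _plane_wave_angle(img[strut_roi])
    ref = _plane_wave_angle(img[reference_roi])
    true_angle = config.pattern_angle_deg if config is not None else ref
    M = math.tan(math.radians(true_angle)) / math.tan(math.radians(inner))
    return PatternObservation(apparent_angle_deg=inner, magnification=M)


def side_view_to_trajectory(
    image: np.ndarray,
    nozzle_od_mm: float = 0.82,
    scale: float | None = None,
    sigma: float = 2.0,
    low_frac: float = 0.5,
    high_frac: float = 1.0,
    nozzle_clearance_px: int = 6,
) -> tuple[StrutTrajectory, float]:
    """Full side-view pipeline: calibrate, find the nozzle, extract contours.

    Returns the trajectory and the mm/px scale used.  If ``scale`` is
    not supplied it is calibrated from the nozzle width; the contour
    search is restricted to rows below the nozzle tip.
    """
    img = to_grayscale(image)
    if scale is None:
        scale = calibrate_scale(img, nozzle_od_mm=nozzle_od_mm)

    # nozzle bottom: last row still containing the near-black bar
    dark = img < 0.08
    noz_rows = np.nonzero(dark.any(axis=1))[0]
    row_start = (noz_rows.max() + nozzle_clearance_px) if len(noz_rows) else 0
    roi = (slice(int(row_start), img.shape[0]), slice(0, img.shape[1]))
    contours = extract_contours(img, sigma=sigma, low_frac=low_frac,
                                high_frac=high_frac, roi=roi)
    return centerline_and_diameter(contours, scale), scale
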