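"""Per-frame 3D localization of astigmatically imaged emitters.

Lateral position comes from an intensity peak search plus background-
subtracted centroid; axial position comes from the two-template normalized
covariance metric inverted through the linear calibration,

    z_rel = ((ξ2 − ξ1)/(ξ1 + ξ2) − b) / a .

This is a single-pass, non-iterative estimator.  An elliptical-Gaussian
least-squares fit is also provided; it is the conventional (slower) width
estimator and serves as the precision reference for the template metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .calibrate import (
    CalibrationCurve,
    metric_from_covariances,
    normalized_covariance,
)

# detection floor for the covariance pair: the maximum of a noise-only ZNCC
# over a 5x5 neighborhood is ~0.15-0.2 (sd ≈ 1/template_side per position),
# so requiring at least one covariance above 0.25 rejects pure background
# while real spots down to SNR ~4 correlate well above 0.4
XI_MIN_DETECT = 0.25

__all__ = [
    "Localization",
    "GaussianFit",
    "find_peak",
    "centroid_xy",
    "axial_position",
    "gaussian_fit",
    "localize_frame",
]


@dataclass(frozen=True)
class Localization:
    """One particle observation in one frame.

    x, y are lateral positions in µm from the image corner; ``z_rel`` is the
    axial position relative to the effective focal plane (µm).  ``xi1``/``xi2``
    are the normalized covariance values used for the axial estimate and
    ``in_range`` records whether the metric fell inside the calibrated span.
    """

    frame: int
    x: float
    y: float
    z_rel: float
    xi1: float
    xi2: float
    photons: float = float("nan")
    snr: float = float("nan")
    in_range: bool = True


def find_peak(image: np.ndarray, center: tuple[int, int], radius: int):
    """Brightest pixel within ``radius`` of ``center`` (row, col), or None.

    The search-window mean background is subtracted before comparison (which
    leaves the argmax unchanged but makes flatness detectable): a window with
    no contrast yields no detection.  Raises if the window lies entirely
    outside the image.
    """
    img = np.asarray(image, dtype=float)
    r0, c0 = int(center[0]), int(center[1])
    rlo, rhi = r0 - radius, r0 + radius + 1
    clo, chi = c0 - radius, c0 + radius + 1
    if rhi <= 0 or chi <= 0 or rlo >= img.shape[0] or clo >= img.shape[1]:
        raise ValueError("search window outside image")
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, img.shape[0]), min(chi, img.shape[1])
    win = img[rlo:rhi, clo:chi]
    if np.ptp(win) == 0:
        return None
    rr, cc = np.unravel_index(int(np.argmax(win)), win.shape)
    return (rlo + rr, clo + cc)


def _window(image, peak, half):
    r, c = peak
    if r - half < 0 or c - half < 0 or r + half >= image.shape[0] or c + half >= image.shape[1]:
        raise ValueError("analysis window extends outside the image")
    return image[r - half : r + half + 1, c - half : c + half + 1]


def _border_mean(win: np.ndarray) -> float:
    mask = np.zeros(win.shape, dtype=bool)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
    return float(win[mask].mean())


def centroid_xy(
    image: np.ndarray,
    peak: tuple[int, int],
    pixel_size: float,
    window: int = 11,
):
    """Background-subtracted intensity centroid around a peak, in µm.

    Local background is the mean of the window's border pixels; negative
    residuals are clipped at zero before weighting.  Returns ``(x, y)`` in µm
    (pixel centres at half-integer pixel coordinates) or None when the window
    holds no positive signal.
    """
    img = np.asarray(image, dtype=float)
    half = window // 2
    win = _window(img, peak, half) - _border_mean(_window(img, peak, half))
    win = np.clip(win, 0.0, None)
    total = win.sum()
    if total <= 0:
        return None
    rows = np.arange(peak[0] - half, peak[0] + half + 1)
    cols = np.arange(peak[1] - half, peak[1] + half + 1)
    cy = float((win.sum(axis=1) * rows).sum() / total)
    cx = float((win.sum(axis=0) * cols).sum() / total)
    return ((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size)


def axial_position(
    image: np.ndarray,
    peak: tuple[int, int],
    curve: CalibrationCurve,
    neighborhood: int = 5,
):
    """Axial position from the template-matching metric at an intensity peak.

    Both templates are correlated with the image patches centred on each
    pixel of a ``neighborhood`` x ``neighborhood`` square around the peak; the
    pixel with the highest ξ1 + ξ2 provides the covariance pair, which the
    calibration line converts to z_rel.  Returns
    ``(z_rel, xi1, xi2, in_range)`` or None when both covariances fall below
    the detection floor.  The result depends only on pixels within
    (template size + neighborhood)/2 of the peak, so cropped and full-frame
    evaluations agree exactly.
    """
    t1, t2 = curve.template_minus, curve.template_plus
    if t1.size != t2.size:
        raise ValueError("template sizes differ")
    half = t1.size // 2 + neighborhood // 2
    crop = _window(np.asarray(image, dtype=float), peak, half)
    m1 = _zncc_small(crop, t1.pixels)
    m2 = _zncc_small(crop, t2.pixels)
    idx = np.unravel_index(int(np.argmax(m1 + m2)), m1.shape)
    xi1, xi2 = float(m1[idx]), float(m2[idx])
    if xi1 < XI_MIN_DETECT and xi2 < XI_MIN_DETECT:
        return None
    metric = float(metric_from_covariances(xi1, xi2))
    z_rel = curve.z_from_metric(metric)
    lo, hi = curve.metric_span
    in_range = lo <= metric <= hi
    return z_rel, xi1, xi2, in_range


def _zncc_small(crop: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Direct Pearson correlation of a template over a small crop.

    Equivalent to :func:`astigtrack.calibrate.normalized_covariance` but
    computed with dense dot products, which is much faster than FFT-based
    matching for the few positions visited per frame.
    """
    s = template.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(crop, (s, s))
    out_shape = win.shape[:2]
    patches = win.reshape(-1, s * s)
    t = template.ravel()
    t = t - t.mean()
    tnorm = np.sqrt((t * t).sum())
    pm = patches.mean(axis=1, keepdims=True)
    num = patches @ t  # means cancel against zero-mean template
    pvar = (patches * patches).sum(axis=1) - patches.shape[1] * pm.ravel() ** 2
    denom = np.sqrt(np.clip(pvar, 0.0, None)) * tnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / denom, 0.0)
    return np.clip(out, -1.0, 1.0).reshape(out_shape)


@dataclass(frozen=True)
class GaussianFit:
    x: float
    y: float
    sigma_x: float
    sigma_y: float
    amplitude: float
    offset: float
    converged: bool


def gaussian_fit(
    image: np.ndarray,
    peak: tuple[int, int],
    pixel_size: float,
    window: int = 11,
) -> GaussianFit:
    """Least-squares elliptical Gaussian fit (pixel-integrated model).

    Positions and widths are returned in µm.  A flat or pathological window
    yields ``converged=False`` with NaN parameters rather than an exception.
    """
    img = np.asarray(image, dtype=float)
    half = window // 2
    win = _window(img, peak, half)
    if np.ptp(win) == 0:
        return GaussianFit(*([float("nan")] * 6), converged=False)

    rows = (np.arange(peak[0] - half, peak[0] + half + 1) + 0.5) * pixel_size
    cols = (np.arange(peak[1] - half, peak[1] + half + 1) + 0.5) * pixel_size
    edge_r = np.concatenate([rows - pixel_size / 2, [rows[-1] + pixel_size / 2]])
    edge_c = np.concatenate([cols - pixel_size / 2, [cols[-1] + pixel_size / 2]])

    def model(params):
        x0, y0, sx, sy, amp, off = params
        fx = 0.5 * np.diff(erf((edge_c - x0) / (abs(sx) * np.sqrt(2))))
        fy = 0.5 * np.diff(erf((edge_r - y0) / (abs(sy) * np.sqrt(2))))
        return off + amp * np.outer(fy, fx)

    off0 = _border_mean(win)
    amp0 = max(win.sum() - off0 * win.size, win.max() - off0)
    p0 = [cols[half], rows[half], 1.5 * pixel_size, 1.5 * pixel_size, amp0, off0]
    try:
        res = least_squares(lambda p: (model(p) - win).ravel(), p0, method="lm", max_nfev=400)
    except Exception:
        return GaussianFit(*([float("nan")] * 6), converged=False)
    x0, y0, sx, sy, amp, off = res.x
    ok = bool(res.success) and amp > 0 and abs(sx) < window * pixel_size
    return GaussianFit(float(x0), float(y0), float(abs(sx)), float(abs(sy)), float(amp), float(off), ok)


def localize_frame(
    image: np.ndarray,
    center: tuple[int, int],
    curve: CalibrationCurve,
    pixel_size: float,
    frame: int = 0,
    search_radius: int = 5,
    window: int = 11,
    neighborhood: int = 5,
    background_sd: float | None = None,
):
    """Full single-particle localization of one frame; None on no detection.

    Combines peak search, lateral centroid and axial template metric into a
    :class:`Localization`.  The photon estimate is the background-subtracted
    window sum (images are assumed photon-calibrated); SNR is the peak
    amplitude above the local background divided by ``background_sd`` (the
    window-border s.d. when not given).
    """
    img = np.asarray(image, dtype=float)
    peak = find_peak(img, center, search_radius)
    if peak is None:
        return None
    half = window // 2
    try:
        win = _window(img, peak, half)
        xy = centroid_xy(img, peak, pixel_size, window)
        axial = axial_position(img, peak, curve, neighborhood)
    except ValueError:
        return None
    if xy is None or axial is None:
        return None
    z_rel, xi1, xi2, in_range = axial
    bg = _border_mean(win)
    mask = np.zeros(win.shape, dtype=bool)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
    sd = float(win[mask].std()) if background_sd is None else background_sd
    photons = float(np.clip(win - bg, 0, None).sum())
    snr = float((win.max() - bg) / sd) if sd > 0 else float("inf")
    return Localization(frame, xy[0], xy[1], z_rel, xi1, xi2, photons, snr, in_range)
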