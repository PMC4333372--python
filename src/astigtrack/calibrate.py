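"""Axial calibration from a bead stack: PSF templates and the linear metric.

Two small templates are cut from a calibration stack below and above the
effective focal plane (by default at z_rel = ±0.4 µm, matching the focal
separation).  Correlating an unknown spot image with both templates yields
normalized covariance values ξ1 and ξ2; the antisymmetric combination
(ξ2 − ξ1)/(ξ1 + ξ2) is, between the two astigmatic focal planes, a linear
function of axial position,

    (ξ2 − ξ1) / (ξ1 + ξ2) = a * z_rel + b,

whose slope and offset form the whole axial calibration.  Normalized
covariance here is the Pearson correlation between the template and an
equal-size image patch (zero-mean normalized cross-correlation), which makes
the metric invariant under affine intensity transforms and hence independent
of photon count over a wide SNR range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import match_template

__all__ = [
    "PsfTemplate",
    "CalibrationCurve",
    "normalized_covariance",
    "extract_templates",
    "fit_calibration",
    "XI_FLOOR",
    "XI_DETECTION",
]

# floor applied to covariance values before forming the ratio metric, to keep
# (xi2 - xi1)/(xi1 + xi2) finite far from focus where correlations go negative
XI_FLOOR = 1e-6
# below this, a covariance value carries no axial information
XI_DETECTION = 0.1


@dataclass(frozen=True)
class PsfTemplate:
    """Square odd-sided PSF subimage with its nominal axial offset (µm)."""

    pixels: np.ndarray
    z_offset: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("template must be square")
        if p.shape[0] % 2 == 0:
            raise ValueError("template side length must be odd")
        if np.ptp(p) == 0:
            raise ValueError("template must not be constant")
        object.__setattr__(self, "pixels", p)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class CalibrationCurve:
    """Linear axial calibration: metric = a * z_rel + b over ``valid_range``.

    ``valid_range`` is the axial span over which the measured metric was
    monotone on the calibration stack; it always contains the inter-focal
    region that the line was fitted on (``fit_range``).  ``residual_max`` is
    the largest absolute deviation of the measured metric from the fitted
    line inside the fit range.
    """

    a: float
    b: float
    template_minus: PsfTemplate
    template_plus: PsfTemplate
    valid_range: tuple[float, float]
    fit_range: tuple[float, float]
    residual_max: float = 0.0

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("calibration slope a must be nonzero")

    @property
    def metric_span(self) -> tuple[float, float]:
        lo = self.a * self.valid_range[0] + self.b
        hi = self.a * self.valid_range[1] + self.b
        return (min(lo, hi), max(lo, hi))

    def z_from_metric(self, metric: float) -> float:
        """Invert the calibration line: z_rel = (metric − b) / a."""
        return (metric - self.b) / self.a

    def to_json(self, path) -> None:
        payload = {
            "a": self.a,
            "b": self.b,
            "valid_range": list(self.valid_range),
            "fit_range": list(self.fit_range),
            "residual_max": self.residual_max,
            "template_minus": {
                "z_offset": self.template_minus.z_offset,
                "pixels": self.template_minus.pixels.tolist(),
            },
            "template_plus": {
                "z_offset": self.template_plus.z_offset,
                "pixels": self.template_plus.pixels.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            a=d["a"],
            b=d["b"],
            template_minus=PsfTemplate(
                np.asarray(d["template_minus"]["pixels"]), d["template_minus"]["z_offset"]
            ),
            template_plus=PsfTemplate(
                np.asarray(d["template_plus"]["pixels"]), d["template_plus"]["z_offset"]
            ),
            valid_range=tuple(d["valid_range"]),
            fit_range=tuple(d["fit_range"]),
            residual_max=d["residual_max"],
        )


def normalized_covariance(image: np.ndarray, template: PsfTemplate) -> np.ndarray:
    """Zero-mean normalized cross-correlation map of a template over an image.

    Each output value is the Pearson correlation between the template and the
    equal-size image patch whose top-left corner is at that output position;
    values lie in [−1, 1] and are invariant under affine intensity transforms
    of the patch.  Positions where the patch (or template) has zero variance
    are defined as 0.  Output shape is ``(H - s + 1, W - s + 1)`` for an
    ``s``-sided template.
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] < template.size or img.shape[1] < template.size:
        raise ValueError("image smaller than template")
    out = match_template(img, template.pixels, pad_input=False)
    out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return np.clip(out, -1.0, 1.0)


def extract_templates(
    stack: np.ndarray,
    z_values,
    offset: float = 0.4,
    size: int = 11,
) -> tuple[PsfTemplate, PsfTemplate]:
    """Cut the two PSF templates at z_rel ≈ ∓offset from a calibration stack.

    Each template is a ``size``-sided subimage centred on the brightest pixel
    of the slice nearest to the requested offset.  Returns
    ``(T1 at -offset, T2 at +offset)``.
    """
    if size % 2 == 0:
        raise ValueError("template size must be odd")
    z = np.asarray(z_values, dtype=float)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != z.size:
        raise ValueError("stack and z list lengths differ")
    step = np.median(np.diff(np.sort(z))) if z.size > 1 else np.inf
    templates = []
    for target in (-offset, +offset):
        i = int(np.argmin(np.abs(z - target)))
        if abs(z[i] - target) > step / 2 + 1e-9:
            raise ValueError(f"no calibration slice within half a step of z = {target}")
        templates.append(PsfTemplate(_cut_centered(stack[i], size), float(z[i])))
    return templates[0], templates[1]


def _cut_centered(image: np.ndarray, size: int) -> np.ndarray:
    h = size // 2
    if image.shape[0] < size or image.shape[1] < size:
        raise ValueError("slice smaller than the requested template size")
    # mild smoothing keeps single noise pixels from hijacking the peak; the
    # search is restricted to positions where a full template fits
    smooth = gaussian_filter(image, 1.0)[h:-h, h:-h]
    r, c = np.unravel_index(int(np.argmax(smooth)), smooth.shape)
    r, c = r + h, c + h
    return image[r - h : r + h + 1, c - h : c + h + 1].copy()


def metric_from_covariances(xi1, xi2):
    """(ξ2 − ξ1)/(ξ1 + ξ2) with values floored at a small positive constant."""
    x1 = np.maximum(xi1, XI_FLOOR)
    x2 = np.maximum(xi2, XI_FLOOR)
    return (x2 - x1) / (x1 + x2)


def slice_covariances(image: np.ndarray, t1: PsfTemplate, t2: PsfTemplate):
    """ξ1, ξ2 at the pixel with the highest ξ1 + ξ2 over a whole image.

    Ties are broken by first occurrence in row-major order (np.argmax).
    """
    m1 = normalized_covariance(image, t1)
    m2 = normalized_covariance(image, t2)
    idx = np.unravel_index(int(np.argmax(m1 + m2)), m1.shape)
    return float(m1[idx]), float(m2[idx])


def fit_calibration(
    stack: np.ndarray,
    z_values,
    t1: PsfTemplate,
    t2: PsfTemplate,
) -> CalibrationCurve:
    """Fit the linear axial calibration from a bead stack and template pair.

    For each slice, ξ1 and ξ2 are read at the pixel maximizing their sum and
    combined into the ratio metric; a least-squares line through metric vs
    z_rel is fitted over the inter-focal region (|z| up to the template
    offset).  The curve's valid range is extended to the largest axial span
    over which the measured metric stays monotone and both covariances stay
    informative.
    """
    z = np.asarray(z_values, dtype=float)
    stack = np.asarray(stack, dtype=float)
    xi1 = np.empty(z.size)
    xi2 = np.empty(z.size)
    for i in range(z.size):
        xi1[i], xi2[i] = slice_covariances(stack[i], t1, t2)
    metric = metric_from_covariances(xi1, xi2)

    offset = max(abs(t1.z_offset), abs(t2.z_offset))
    in_fit = (z >= -offset - 1e-9) & (z <= offset + 1e-9)
    usable = in_fit & ((xi1 >= XI_DETECTION) | (xi2 >= XI_DETECTION))
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable calibration slices in the inter-focal range")
    a, b = np.polyfit(z[usable], metric[usable], 1)
    residual_max = float(np.max(np.abs(metric[usable] - (a * z[usable] + b))))

    valid = _monotone_span(z, metric, xi1, xi2, offset, rising=a > 0)
    return CalibrationCurve(
        a=float(a),
        b=float(b),
        template_minus=t1,
        template_plus=t2,
        valid_range=valid,
        fit_range=(float(z[usable].min()), float(z[usable].max())),
        residual_max=residual_max,
    )


def _monotone_span(z, metric, xi1, xi2, offset, rising: bool) -> tuple[float, float]:
    """Largest z interval containing [-offset, offset] with monotone metric."""
    order = np.argsort(z)
    z, metric = z[order], metric[order]
    informative = (xi1[order] >= XI_DETECTION) | (xi2[order] >= XI_DETECTION)
    sign = 1.0 if rising else -1.0
    centre = int(np.argmin(np.abs(z)))
    lo = centre
    while lo > 0 and informative[lo - 1] and sign * (metric[lo] - metric[lo - 1]) > 0:
        lo -= 1
    hi = centre
    n = z.size
    while hi < n - 1 and informative[hi + 1] and sign * (metric[hi + 1] - metric[hi]) > 0:
        hi += 1
    z_lo = min(float(z[lo]), -offset)
    z_hi = max(float(z[hi]), offset)
    return (z_lo, z_hi)
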