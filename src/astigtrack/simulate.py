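"""Synthetic data generation for astigmatic 3D single-particle tracking.

Provides a parametric astigmatic point-spread function (PSF), an EMCCD-like
camera model, rendering of single frames and axial calibration stacks, and
Brownian-motion trajectory simulation with optional Markov switching between
mobility states.  Everything downstream (calibration, localization, feedback,
trajectory statistics) is exercised against these generators, so their
defaults describe the experimental regime being emulated: 100-400 photons
per signal, background noise of ~2 photons/pixel (s.d.), SNR roughly 4-65,
frame intervals of 1-20 ms.

Conventions: lengths in micrometres, times in seconds.  The image origin is
the field corner; pixel ``i`` spans ``[i*px, (i+1)*px)`` so its centre sits at
``(i + 0.5) * px``.  z increases away from the objective; ``z_rel = 0`` is the
effective focal plane where the x and y PSF widths are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "PsfModel",
    "CameraModel",
    "MotionModel",
    "psf_width",
    "render_frame",
    "render_calibration_stack",
    "simulate_path",
    "photons_for_snr",
]


@dataclass(frozen=True)
class PsfModel:
    """Astigmatic PSF: Gaussian-beam width law per axis with split focal planes.

    sigma(z) = sigma0 * sqrt(1 + ((z - z_focus) / depth_scale)^2), with the x
    focal plane at ``-focal_separation/2`` and the y focal plane at
    ``+focal_separation/2``.  The effective focal plane (equal widths) is at
    z_rel = 0 by symmetry.

    Parameters
    ----------
    sigma0 : float
        In-focus Gaussian width of one axis (µm).
    depth_scale : float
        Axial distance over which the width grows by sqrt(2) (µm).
    focal_separation : float
        Distance between the x and y focal planes (µm); the amount of
        astigmatism introduced by the cylindrical lens.
    """

    sigma0: float = 0.16
    depth_scale: float = 0.4
    focal_separation: float = 0.8

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.depth_scale <= 0 or self.focal_separation < 0:
            raise ValueError("PsfModel parameters must be positive")

    @property
    def focus_x(self) -> float:
        return -self.focal_separation / 2.0

    @property
    def focus_y(self) -> float:
        return +self.focal_separation / 2.0


@dataclass(frozen=True)
class CameraModel:
    """EMCCD-like camera: pixel size, background, shot/read noise.

    ``em_excess_factor`` inflates shot noise by the excess-noise factor of
    electron multiplication (variance F^2 * mean); read noise is additive
    Gaussian.  ``background_sd`` is the nominal background standard deviation
    used for SNR bookkeeping; the rendered background fluctuation is
    F^2 * background_mean + read_noise_sd^2 which the defaults keep at
    ~2 photons/pixel.
    """

    pixel_size: float = 0.24
    background_mean: float = 2.0
    background_sd: float = 2.0
    read_noise_sd: float = 0.5
    em_excess_factor: float = np.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("background_mean", "background_sd", "read_noise_sd", "em_excess_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def effective_background_sd(self) -> float:
        """Background s.d. implied by the rendering noise model (photons/pixel)."""
        return float(
            np.sqrt(
                self.em_excess_factor**2 * self.background_mean + self.read_noise_sd**2
            )
        )


@dataclass(frozen=True)
class MotionModel:
    """Brownian motion with optional Markov switching between mobility states.

    Parameters
    ----------
    diffusion_coefficients : tuple of float
        One D per state (µm²/s).
    switching_rates : tuple of tuple of float, optional
        Square rate matrix (1/s); entry [i][j] is the rate of leaving state i
        for state j.  Diagonal entries are ignored.  None or an all-zero
        matrix means no switching.
    dimensionality : {"3d", "2d"}
        "2d" confines motion to the xy plane (membrane-like); "3d" is free
        diffusion.
    frame_interval : float
        Time between observations, Δt (s).
    """

    diffusion_coefficients: tuple[float, ...] = (1.0,)
    switching_rates: tuple[tuple[float, ...], ...] | None = None
    dimensionality: str = "3d"
    frame_interval: float = 0.0165

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.diffusion_coefficients):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.dimensionality not in ("2d", "3d"):
            raise ValueError("dimensionality must be '2d' or '3d'")
        if self.switching_rates is not None:
            m = len(self.diffusion_coefficients)
            rates = self.switching_rates
            if len(rates) != m or any(len(row) != m for row in rates):
                raise ValueError("switching_rates must be an m x m matrix")
            if any(r < 0 for row in rates for r in row):
                raise ValueError("switching rates must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.diffusion_coefficients)

    @property
    def ndim(self) -> int:
        return 2 if self.dimensionality == "2d" else 3


def psf_width(z_rel, axis: str, model: PsfModel):
    """Gaussian width of the PSF along one axis at axial position ``z_rel``.

    Minimal (= ``sigma0``) at that axis's own focal plane and strictly
    increasing away from it.  Accepts scalars or arrays.
    """
    if axis == "x":
        z0 = model.focus_x
    elif axis == "y":
        z0 = model.focus_y
    else:
        raise ValueError("axis must be 'x' or 'y'")
    z = np.asarray(z_rel, dtype=float)
    w = model.sigma0 * np.sqrt(1.0 + ((z - z0) / model.depth_scale) ** 2)
    return float(w) if np.isscalar(z_rel) else w


def _pixel_fractions(centre: float, sigma: float, n: int, px: float) -> np.ndarray:
    """Fraction of a 1-D Gaussian (centre, sigma in µm) inside each of n pixels."""
    edges = np.arange(n + 1) * px
    c = erf((edges - centre) / (sigma * np.sqrt(2.0)))
    return 0.5 * np.diff(c)


def render_frame(
    emitters,
    psf: PsfModel,
    cam: CameraModel,
    shape: tuple[int, int] = (32, 32),
    noise: bool = True,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render one camera frame containing point emitters.

    Each emitter is ``(x, y, z_rel, photons)`` with x, y in µm from the field
    corner.  The elliptical Gaussian of each emitter (widths from
    :func:`psf_width` at its z_rel) is integrated over the pixel grid so that
    the total signal equals the photon count; a uniform background is added.
    With ``noise=True``, Poisson shot noise on signal + background is scaled
    by the EM excess factor and Gaussian read noise is added.

    Returns a float image in photon units, shape ``(ny, nx)`` indexed
    ``[row=y, col=x]``.
    """
    ny, nx = shape
    img = np.full((ny, nx), float(cam.background_mean))
    px = cam.pixel_size
    for (x, y, z_rel, photons) in emitters:
        if photons < 0:
            raise ValueError("photon count must be >= 0")
        if not (0.0 <= x <= nx * px and 0.0 <= y <= ny * px):
            raise ValueError(f"emitter at ({x:.3f}, {y:.3f}) outside the image field")
        if photons == 0:
            continue
        fx = _pixel_fractions(x, psf_width(z_rel, "x", psf), nx, px)
        fy = _pixel_fractions(y, psf_width(z_rel, "y", psf), ny, px)
        img += photons * np.outer(fy, fx)
    if noise:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        shot = gen.poisson(img).astype(float)
        img = img + cam.em_excess_factor * (shot - img)
        if cam.read_noise_sd > 0:
            img += gen.normal(0.0, cam.read_noise_sd, size=img.shape)
    return img


def render_calibration_stack(
    psf: PsfModel,
    cam: CameraModel,
    z_min: float = -1.0,
    z_max: float = 1.0,
    step: float = 0.05,
    photons: float = 5000.0,
    shape: tuple[int, int] = (32, 32),
    noise: bool = False,
    rng: np.random.Generator | int | None = None,
):
    """Render a bead calibration stack: one centred emitter stepped through z.

    Emulates moving an immobilised bead through the focal plane with the
    piezo stage, by default in 50 nm steps.  Returns ``(stack, z_values)``
    with ``stack`` of shape ``(n_slices, ny, nx)``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if z_min >= z_max:
        raise ValueError("empty axial range: require z_min < z_max")
    n = int(np.floor((z_max - z_min) / step + 1e-9)) + 1
    z_values = z_min + step * np.arange(n)
    ny, nx = shape
    # centre of the middle pixel
    cx = (nx // 2 + 0.5) * cam.pixel_size
    cy = (ny // 2 + 0.5) * cam.pixel_size
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    stack = np.stack(
        [
            render_frame([(cx, cy, z, photons)], psf, cam, shape, noise=noise, rng=gen)
            for z in z_values
        ]
    )
    return stack, z_values


def simulate_path(
    motion: MotionModel,
    n_steps: int,
    start_state: int = 0,
    rng: np.random.Generator | int | None = None,
    start_position=(0.0, 0.0, 0.0),
):
    """Simulate a Brownian trajectory with Markov mobility-state switching.

    Per-axis increments are Gaussian with variance ``2 * D(state) * Δt``; the
    state evolves as a discrete-time Markov chain whose per-frame switching
    probabilities derive from the continuous rates as ``1 - exp(-rate * Δt)``.
    For "2d" motion z stays constant.

    Returns
    -------
    positions : ndarray, shape (n_steps + 1, 3)
    states : ndarray of int, shape (n_steps + 1,)
        State labels aligned with positions; the increment from position i to
        i + 1 is drawn with ``D(states[i])``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0 <= start_state < motion.n_states:
        raise ValueError("start_state out of range")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    dt = motion.frame_interval
    m = motion.n_states

    states = np.empty(n_steps + 1, dtype=np.int64)
    states[0] = start_state
    if motion.switching_rates is not None and m > 1:
        rates = np.asarray(motion.switching_rates, dtype=float)
        np.fill_diagonal(rates, 0.0)
        # per-frame transition matrix: leave state i with prob 1 - exp(-total*dt),
        # split between destinations proportionally to their rates
        P = np.zeros((m, m))
        for i in range(m):
            total = rates[i].sum()
            if total > 0:
                p_leave = 1.0 - np.exp(-total * dt)
                P[i] = p_leave * rates[i] / total
            P[i, i] = 1.0 - P[i].sum()
        u = gen.random(n_steps)
        cum = np.cumsum(P, axis=1)
        for t in range(n_steps):
            states[t + 1] = np.searchsorted(cum[states[t]], u[t], side="right")
    else:
        states[:] = start_state

    D = np.asarray(motion.diffusion_coefficients, dtype=float)[states[:-1]]
    sd = np.sqrt(2.0 * D * dt)
    increments = gen.normal(size=(n_steps, 3)) * sd[:, None]
    if motion.ndim == 2:
        increments[:, 2] = 0.0
    positions = np.empty((n_steps + 1, 3))
    positions[0] = np.asarray(start_position, dtype=float)
    positions[1:] = positions[0] + np.cumsum(increments, axis=0)
    return positions, states


def photons_for_snr(snr: float, psf: PsfModel, cam: CameraModel, z_rel: float = 0.0) -> float:
    """Photon count giving a target SNR for a pixel-centred emitter at z_rel.

    SNR is defined as the peak pixel amplitude above the mean background
    divided by the background standard deviation (the camera's nominal
    ``background_sd``).
    """
    px = cam.pixel_size
    fx = _pixel_fractions(0.5 * px, psf_width(z_rel, "x", psf), 1, px)[0]
    fy = _pixel_fractions(0.5 * px, psf_width(z_rel, "y", psf), 1, px)[0]
    peak_fraction = fx * fy
    return snr * cam.background_sd / peak_fraction
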