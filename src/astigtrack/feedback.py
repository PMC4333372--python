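"""Closed-loop axial feedback tracking, simulated end to end.

The real instrument re-centres its focal plane on the tracked particle every
frame: the axial estimate from the current frame is converted into a piezo
stage move applied before the next frame, so the particle stays within the
narrow axial detection range indefinitely (until photobleaching).  Here the
whole loop is emulated in software: a Brownian particle is rendered through
the astigmatic PSF at its current offset from the focal plane, localized
with the template metric, and the stage is moved with a configurable gain
and latency.  Absolute axial coordinates are recovered by adding the stage
trace back to the relative localizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import CalibrationCurve
from .localize import Localization, localize_frame
from .simulate import CameraModel, MotionModel, PsfModel, render_frame, simulate_path

__all__ = [
    "StageTrace",
    "ClosedLoopResult",
    "feedback_step",
    "run_closed_loop",
    "absolute_z",
]


@dataclass
class StageTrace:
    """Per-frame focal-plane position and the move commanded after each frame.

    ``stage_z`` is the focal-plane position expressed in specimen coordinates
    (so absolute particle positions are ``stage_z + z_rel``); ``move`` is the
    commanded sample move, whose application *lowers* ``stage_z`` by the same
    amount (moving the sample down brings the focal plane up relative to the
    specimen).
    """

    stage_z: np.ndarray
    move: np.ndarray
    latency: int = 1
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.stage_z = np.asarray(self.stage_z, dtype=float)
        self.move = np.asarray(self.move, dtype=float)
        if self.stage_z.shape != self.move.shape:
            raise ValueError("stage_z and move must have equal length")
        if self.latency < 1:
            raise ValueError("latency must be >= 1 frame")


def feedback_step(z_rel: float, gain: float = 1.0, in_range: bool = True) -> float:
    """Proportional axial correction: move = −gain · z_rel; hold if out of range."""
    if not in_range or not np.isfinite(z_rel):
        return 0.0
    return -gain * float(z_rel)


def absolute_z(z_rel, stage_z):
    """Absolute axial coordinate: z_abs = stage_z + z_rel, elementwise."""
    zr = np.asarray(z_rel, dtype=float)
    sz = np.asarray(stage_z, dtype=float)
    if zr.shape != sz.shape:
        raise ValueError("z_rel and stage_z lengths differ")
    return zr + sz


@dataclass
class ClosedLoopResult:
    localizations: list
    stage: StageTrace
    true_positions: np.ndarray
    true_states: np.ndarray
    retained: bool
    n_tracked: int
    loss_frame: int | None = None


def run_closed_loop(
    motion: MotionModel,
    psf: PsfModel,
    cam: CameraModel,
    curve: CalibrationCurve,
    n_frames: int,
    photons: float = 300.0,
    latency: int = 1,
    gain: float = 1.0,
    capture_range: float = 1.0,
    start_z_rel: float = 0.0,
    roi: tuple[int, int] = (21, 21),
    max_misses: int = 3,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
    path: np.ndarray | None = None,
) -> ClosedLoopResult:
    """Simulate feedback tracking of one Brownian particle.

    Each frame the particle is rendered at its true position relative to the
    current focal plane, localized, and the axial estimate (clamped to the
    calibration's valid range) is turned into a stage move applied
    ``latency`` frames later.  Lateral motion is followed by re-centring the
    rendered region of interest on the previous localization, mimicking the
    on-camera search window of the real tracker.

    The run ends early — ``retained=False`` — when the particle's true axial
    offset exceeds ``capture_range`` or localization fails ``max_misses``
    frames in a row.  A particle already outside the capture range at frame 0
    is an error.  A deterministic ``path`` of shape (n_frames, 3) may be
    supplied instead of simulating Brownian motion (e.g. constant-velocity
    test inputs).
    """
    if abs(start_z_rel) > capture_range:
        raise ValueError("particle not within capture range at start")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if path is not None:
        positions = np.asarray(path, dtype=float)
        if positions.shape != (n_frames, 3):
            raise ValueError("path must have shape (n_frames, 3)")
        states = np.zeros(n_frames, dtype=np.int64)
    elif n_frames > 1:
        positions, states = simulate_path(motion, n_frames - 1, rng=gen)
    else:
        positions, states = np.zeros((1, 3)), np.zeros(1, dtype=np.int64)
    positions = positions + np.array([0.0, 0.0, start_z_rel])

    ny, nx = roi
    px = cam.pixel_size
    # ROI origin in specimen coordinates; start with the particle centred
    roi_x = positions[0, 0] - (nx // 2 + 0.5) * px
    roi_y = positions[0, 1] - (ny // 2 + 0.5) * px

    z_lo, z_hi = curve.valid_range
    stage_z = np.zeros(n_frames)
    moves = np.zeros(n_frames)
    locs: list[Localization | None] = []
    misses = 0
    retained = True
    loss_frame: int | None = None

    for t in range(n_frames):
        if t > 0:
            # the move commanded after frame t - latency is applied before frame
            # t; a commanded sample move of -z_rel raises the focal plane in
            # specimen coordinates by +z_rel, so stage_z decreases by the move
            applied = moves[t - latency] if t - latency >= 0 else 0.0
            stage_z[t] = stage_z[t - 1] - applied
        z_off = positions[t, 2] - stage_z[t]
        if abs(z_off) > capture_range:
            if t == 0:
                raise ValueError("particle not within capture range at start")
            retained = False
            loss_frame = t
            stage_z = stage_z[:t]
            moves = moves[:t]
            break
        ex = positions[t, 0] - roi_x
        ey = positions[t, 1] - roi_y
        if not (0 < ex < nx * px and 0 < ey < ny * px):
            loc = None  # wandered out of the rendered region: lost laterally
        else:
            img = render_frame([(ex, ey, z_off, photons)], psf, cam, roi, noise=noise, rng=gen)
            loc = localize_frame(
                img,
                (ny // 2, nx // 2),
                curve,
                px,
                frame=t,
                background_sd=cam.background_sd,
            )
        if loc is None:
            misses += 1
            move = 0.0
            locs.append(None)
            if misses >= max_misses:
                retained = False
                loss_frame = t
                stage_z = stage_z[: t + 1]
                moves = moves[: t + 1]
                break
        else:
            misses = 0
            z_est = float(np.clip(loc.z_rel, z_lo, z_hi))
            move = feedback_step(z_est, gain, in_range=loc.in_range)
            # express the localization in specimen coordinates
            locs.append(
                Localization(
                    frame=t,
                    x=loc.x + roi_x,
                    y=loc.y + roi_y,
                    z_rel=loc.z_rel,
                    xi1=loc.xi1,
                    xi2=loc.xi2,
                    photons=loc.photons,
                    snr=loc.snr,
                    in_range=loc.in_range,
                )
            )
            # re-centre the ROI on the localization (integer pixels)
            roi_x += (round(loc.x / px - 0.5) - nx // 2) * px
            roi_y += (round(loc.y / px - 0.5) - ny // 2) * px
        moves[t] = move

    n_tracked = len(stage_z)
    trace = StageTrace(stage_z=stage_z, move=moves, latency=latency, gain=gain)
    return ClosedLoopResult(
        localizations=locs[:n_tracked],
        stage=trace,
        true_positions=positions[:n_tracked],
        true_states=states[:n_tracked],
        retained=retained,
        n_tracked=n_tracked,
        loss_frame=loss_frame,
    )
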