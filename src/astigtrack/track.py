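"""Offline particle detection, nearest-neighbour linking, trajectory assembly.

Post-processing recovers every particle in a movie (not just the one the
feedback loop followed): frames are cross-correlated with the two PSF
templates, local maxima of the correlation above a threshold become
candidate spots, and candidates are refined with the same centroid/axial
estimators used online.  Localizations are linked across frames by a
mutual-nearest-neighbour rule with a user-supplied displacement limit; any
ambiguity (a localization with several candidate partners within the limit)
terminates the trajectories involved, which is the conservative behaviour
appropriate at the very low emitter densities (< 1 pM) this is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import match_template, peak_local_max

from .calibrate import CalibrationCurve
from .feedback import StageTrace, absolute_z
from .localize import Localization, axial_position, centroid_xy

__all__ = [
    "Trajectory",
    "detect_particles",
    "link_nearest_neighbor",
    "assemble_absolute",
]

MIN_TRAJECTORY_LENGTH = 3


@dataclass
class Trajectory:
    """Time-ordered particle track; frames strictly consecutive (no gaps)."""

    frames: np.ndarray
    t_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z_rel: np.ndarray
    z_abs: np.ndarray | None = None
    photons: np.ndarray | None = None
    traj_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        for name in ("t_s", "x", "y", "z_rel"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.frames) == 1):
            raise ValueError("trajectory frames must increase strictly by 1")
        n = self.frames.size
        for name in ("t_s", "x", "y", "z_rel"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} length mismatch")

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def xyz(self) -> np.ndarray:
        z = self.z_abs if self.z_abs is not None else self.z_rel
        return np.column_stack([self.x, self.y, z])


def detect_particles(
    image: np.ndarray,
    curve: CalibrationCurve,
    pixel_size: float,
    threshold: float = 0.4,
    frame: int = 0,
    window: int = 11,
    neighborhood: int = 5,
) -> list[Localization]:
    """All particles in one frame via template correlation maxima.

    The detection map is the pixelwise maximum of the normalized covariance
    with the two calibration templates (computed full-frame, image-sized via
    padding); local maxima above ``threshold`` separated by at least one
    template width are refined by centroid and axial estimation.  Candidates
    too close to the border for the analysis windows are dropped.
    """
    img = np.asarray(image, dtype=float)
    t1, t2 = curve.template_minus, curve.template_plus
    m1 = np.nan_to_num(match_template(img, t1.pixels, pad_input=True))
    m2 = np.nan_to_num(match_template(img, t2.pixels, pad_input=True))
    score = np.maximum(m1, m2)
    peaks = peak_local_max(
        score, min_distance=t1.size // 2, threshold_abs=threshold, exclude_border=False
    )
    out: list[Localization] = []
    for r, c in peaks:
        try:
            xy = centroid_xy(img, (r, c), pixel_size, window)
            axial = axial_position(img, (r, c), curve, neighborhood)
        except ValueError:
            continue
        if xy is None or axial is None:
            continue
        z_rel, xi1, xi2, in_range = axial
        out.append(Localization(frame, xy[0], xy[1], z_rel, xi1, xi2, in_range=in_range))
    return out


def _positions(locs: list[Localization], dims: str) -> np.ndarray:
    if dims == "xy":
        return np.array([[l.x, l.y] for l in locs], dtype=float).reshape(len(locs), -1)
    return np.array([[l.x, l.y, l.z_rel] for l in locs], dtype=float).reshape(len(locs), -1)


def link_nearest_neighbor(
    localizations_by_frame: dict[int, list[Localization]],
    max_displacement: float,
    frame_interval: float,
    dims: str = "xyz",
    min_length: int = MIN_TRAJECTORY_LENGTH,
) -> list[Trajectory]:
    """Link per-frame localizations into trajectories by mutual nearest neighbours.

    A link between consecutive frames requires the two localizations to be
    each other's unique nearest neighbour within ``max_displacement`` (µm,
    measured in ``dims``: "xy" lateral or "xyz").  If any localization has
    two or more candidate partners within the limit, the situation is
    ambiguous and every trajectory involved is terminated at that frame.
    Trajectories shorter than ``min_length`` are discarded.
    """
    frames = sorted(localizations_by_frame)
    active: dict[int, list[Localization]] = {}  # open trajectories keyed by id
    finished: list[list[Localization]] = []
    next_id = 0
    prev_locs: list[Localization] = []
    prev_ids: list[int] = []

    for fi, f in enumerate(frames):
        curr = list(localizations_by_frame[f])
        new_ids: list[int] = [-1] * len(curr)
        if prev_locs and curr and (fi == 0 or frames[fi - 1] == f - 1):
            d = cdist(_positions(prev_locs, dims), _positions(curr, dims))
            within = d <= max_displacement
            amb_prev = within.sum(axis=1) >= 2
            amb_curr = within.sum(axis=0) >= 2
            for i, loc_prev in enumerate(prev_locs):
                cand = np.flatnonzero(within[i])
                if cand.size != 1:
                    continue  # zero candidates (track ends) or ambiguous
                j = int(cand[0])
                if amb_prev[i] or amb_curr[j]:
                    continue  # ambiguity: terminate (do not link)
                tid = prev_ids[i]
                active[tid].append(curr[j])
                new_ids[j] = tid
        elif prev_locs:
            pass  # frame gap: all open trajectories terminate

        # close trajectories that found no continuation
        for tid in list(active):
            if tid in prev_ids and tid not in new_ids:
                finished.append(active.pop(tid))
        # start new trajectories for unlinked localizations
        for j, loc in enumerate(curr):
            if new_ids[j] == -1:
                active[next_id] = [loc]
                new_ids[j] = next_id
                next_id += 1
        prev_locs = curr
        prev_ids = new_ids
    finished.extend(active.values())

    out = []
    for tid, locs in enumerate(sorted(finished, key=lambda ls: (ls[0].frame, ls[0].x))):
        if len(locs) < min_length:
            continue
        out.append(
            Trajectory(
                frames=[l.frame for l in locs],
                t_s=[l.frame * frame_interval for l in locs],
                x=[l.x for l in locs],
                y=[l.y for l in locs],
                z_rel=[l.z_rel for l in locs],
                photons=np.array([l.photons for l in locs]),
                traj_id=len(out),
            )
        )
    return out


def assemble_absolute(trajectories: list[Trajectory], stage: StageTrace) -> list[Trajectory]:
    """Attach absolute axial coordinates using the recorded stage trace."""
    n = stage.stage_z.size
    out = []
    for traj in trajectories:
        if traj.frames.min() < 0 or traj.frames.max() >= n:
            raise ValueError("stage trace does not cover trajectory frames")
        z_abs = absolute_z(traj.z_rel, stage.stage_z[traj.frames])
        out.append(
            Trajectory(
                frames=traj.frames,
                t_s=traj.t_s,
                x=traj.x,
                y=traj.y,
                z_rel=traj.z_rel,
                z_abs=z_abs,
                photons=traj.photons,
                traj_id=traj.traj_id,
            )
        )
    return out
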