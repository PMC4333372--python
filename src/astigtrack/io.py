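"""File formats and run configuration.

Movies are multi-frame grayscale TIFF (16-bit unsigned or 32-bit float);
trajectories and stage traces are plain CSV; calibration curves and ground
truth go to JSON.  ``RunConfig`` gathers every tunable parameter of the
pipeline, is strict about unknown keys, and can be round-tripped through
YAML/JSON so each run can write its resolved configuration next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import tifffile
import yaml

from .feedback import StageTrace
from .track import Trajectory

__all__ = [
    "read_movie",
    "write_movie",
    "read_trajectories",
    "write_trajectories",
    "read_stage_trace",
    "write_stage_trace",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
]

TRAJECTORY_COLUMNS = ["traj_id", "frame", "t_s", "x_um", "y_um", "zrel_um", "zabs_um", "photons"]


def write_movie(stack: np.ndarray, path) -> None:
    """Write an image stack as multi-frame grayscale TIFF (uint16 or float32)."""
    arr = np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, y, x) array")
    if arr.dtype == np.uint16:
        out = arr
    else:
        out = arr.astype(np.float32)
    tifffile.imwrite(path, out, photometric="minisblack")


def read_movie(path) -> np.ndarray:
    """Read a multi-frame grayscale TIFF; rejects RGB/colour input."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise ValueError("expected a grayscale stack; got colour (multi-sample) data")
            arr = tif.asarray()
    except ValueError:
        raise
    except Exception as exc:  # not a TIFF
        raise ValueError(f"cannot read {path} as TIFF: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected a grayscale stack; got higher-dimensional data")
    return arr


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    rows = []
    for traj in trajectories:
        zabs = traj.z_abs if traj.z_abs is not None else np.full(len(traj), np.nan)
        photons = traj.photons if traj.photons is not None else np.full(len(traj), np.nan)
        for i in range(len(traj)):
            rows.append(
                dict(
                    traj_id=traj.traj_id,
                    frame=int(traj.frames[i]),
                    t_s=traj.t_s[i],
                    x_um=traj.x[i],
                    y_um=traj.y[i],
                    zrel_um=traj.z_rel[i],
                    zabs_um=zabs[i],
                    photons=photons[i],
                )
            )
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV; validates schema and per-trajectory frame order."""
    df = pd.read_csv(path)
    required = [c for c in TRAJECTORY_COLUMNS if c != "photons"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"trajectory file missing column '{col}'")
    if df.duplicated(subset=["traj_id", "frame"]).any():
        raise ValueError("duplicate (traj_id, frame) rows")
    has_photons = "photons" in df.columns
    out = []
    for tid, group in df.groupby("traj_id", sort=True):
        g = group.sort_values("frame")
        d = np.diff(g["frame"].to_numpy())
        if np.any(d <= 0):
            raise ValueError(f"frames not strictly increasing for traj_id {tid} (column 'frame')")
        zabs = g["zabs_um"].to_numpy()
        out.append(
            Trajectory(
                frames=g["frame"].to_numpy(),
                t_s=g["t_s"].to_numpy(),
                x=g["x_um"].to_numpy(),
                y=g["y_um"].to_numpy(),
                z_rel=g["zrel_um"].to_numpy(),
                z_abs=None if np.all(np.isnan(zabs)) else zabs,
                photons=g["photons"].to_numpy() if has_photons else None,
                traj_id=int(tid),
            )
        )
    return out


def write_stage_trace(stage: StageTrace, path) -> None:
    pd.DataFrame(
        dict(
            frame=np.arange(stage.stage_z.size),
            stage_z_um=stage.stage_z,
            move_um=stage.move,
        )
    ).to_csv(path, index=False)


def read_stage_trace(path, latency: int = 1, gain: float = 1.0) -> StageTrace:
    df = pd.read_csv(path)
    for col in ("frame", "stage_z_um", "move_um"):
        if col not in df.columns:
            raise ValueError(f"stage trace missing column '{col}'")
    df = df.sort_values("frame")
    return StageTrace(
        stage_z=df["stage_z_um"].to_numpy(),
        move=df["move_um"].to_numpy(),
        latency=latency,
        gain=gain,
    )


def write_ground_truth(path, **arrays) -> None:
    """Sidecar JSON with ground truth (positions, states, parameters, seed)."""
    payload = {}
    for key, val in arrays.items():
        if isinstance(val, np.ndarray):
            payload[key] = val.tolist()
        elif isinstance(val, (np.integer, np.floating)):
            payload[key] = val.item()
        else:
            payload[key] = val
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _strict(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PsfConfig:
    sigma0: float = 0.16
    depth_scale: float = 0.4
    focal_separation: float = 0.8


@dataclass
class CameraConfig:
    pixel_size: float = 0.24
    background_mean: float = 2.0
    background_sd: float = 2.0
    read_noise_sd: float = 0.5
    em_excess_factor: float = 1.4142135623730951


@dataclass
class MotionConfig:
    diffusion_coefficients: list = field(default_factory=lambda: [1.0])
    switching_rates: list | None = None
    dimensionality: str = "3d"
    frame_interval: float = 0.0165


@dataclass
class CalibrationConfig:
    z_min: float = -1.0
    z_max: float = 1.0
    step: float = 0.05
    photons: float = 5000.0
    template_offset: float = 0.4
    template_size: int = 11


@dataclass
class FeedbackConfig:
    n_frames: int = 1000
    photons: float = 300.0
    latency: int = 1
    gain: float = 1.0
    capture_range: float = 1.0


@dataclass
class LinkingConfig:
    max_displacement: float = 0.8
    dims: str = "xyz"
    detection_threshold: float = 0.4


@dataclass
class FittingConfig:
    n_components: int = 2
    dims: str = "xy"


@dataclass
class StatesConfig:
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; strict on unknown keys."""

    psf: PsfConfig = field(default_factory=PsfConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    states: StatesConfig = field(default_factory=StatesConfig)
    seed: int = 0
    output_dir: str = "."

    _SECTIONS = {
        "psf": PsfConfig,
        "camera": CameraConfig,
        "motion": MotionConfig,
        "calibration": CalibrationConfig,
        "feedback": FeedbackConfig,
        "linking": LinkingConfig,
        "fitting": FittingConfig,
        "states": StatesConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls._SECTIONS) | {"seed", "output_dir"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _strict(section_cls, dict(data[name]), name)
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "output_dir" in data:
            kwargs["output_dir"] = str(data["output_dir"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_resolved(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # convenience constructors of the runtime models
    def psf_model(self):
        from .simulate import PsfModel

        return PsfModel(**dataclasses.asdict(self.psf))

    def camera_model(self):
        from .simulate import CameraModel

        return CameraModel(**dataclasses.asdict(self.camera))

    def motion_model(self):
        from .simulate import MotionModel

        d = dataclasses.asdict(self.motion)
        d["diffusion_coefficients"] = tuple(d["diffusion_coefficients"])
        if d["switching_rates"] is not None:
            d["switching_rates"] = tuple(tuple(row) for row in d["switching_rates"])
        return MotionModel(**d)
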