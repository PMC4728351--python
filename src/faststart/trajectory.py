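"""Container for one trial's tracked escape trajectory.

A trial is a pair of dorsally tracked markers — the centre of mass (CoM)
and the snout tip — sampled at a fixed frame rate (240 Hz in the reference
protocol), together with the stimulus timing and geometry needed for
latency and the stimulus covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Permitted non-uniformity of the timestamp grid, in seconds.
TIME_TOL_S = 1e-9


@dataclass
class TrackedTrajectory:
    """Time-stamped CoM + snout coordinates for a single stimulation trial.

    Coordinates are in cm in a fixed laboratory frame (y up, angles
    counterclockwise-positive); frames are 0-based.
    """

    frames: np.ndarray          # (n,) int frame indices
    time_s: np.ndarray          # (n,) uniform timestamps = frame / frame_rate
    com_xy_cm: np.ndarray       # (n, 2)
    snout_xy_cm: np.ndarray     # (n, 2)
    frame_rate_hz: float
    stimulus_frame: int         # frame of first stimulus-water contact
    stimulus_xy_cm: tuple[float, float]
    fish_id: str = "fish"
    trial_number: int = 1
    tl_cm: float = float("nan")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.com_xy_cm = np.asarray(self.com_xy_cm, dtype=float)
        self.snout_xy_cm = np.asarray(self.snout_xy_cm, dtype=float)
        n = len(self.frames)
        if not (len(self.time_s) == self.com_xy_cm.shape[0] == self.snout_xy_cm.shape[0] == n):
            raise ValueError("frames, time_s, com_xy_cm and snout_xy_cm lengths differ")
        if n < 1:
            raise ValueError("empty trajectory")
        if self.com_xy_cm.shape[1:] != (2,) or self.snout_xy_cm.shape[1:] != (2,):
            raise ValueError("coordinates must be (n, 2) arrays")
        if self.frame_rate_hz <= 0 or not np.isfinite(self.frame_rate_hz):
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        if len(np.unique(self.frames)) != n:
            raise ValueError("duplicate frame indices")
        if n >= 2:
            dts = np.diff(self.time_s)
            if np.any(dts <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.max(np.abs(dts - 1.0 / self.frame_rate_hz)) > TIME_TOL_S:
                raise ValueError("timestamps are not uniform at the stated frame rate")
        if not (np.isfinite(self.com_xy_cm).all() and np.isfinite(self.snout_xy_cm).all()):
            raise ValueError("non-finite coordinates")
        if not (self.frames[0] <= self.stimulus_frame <= self.frames[-1]):
            raise ValueError(
                f"stimulus_frame {self.stimulus_frame} outside recorded range "
                f"[{self.frames[0]}, {self.frames[-1]}]"
            )

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def index_of_frame(self, frame: int) -> int:
        """Array index of an absolute frame number."""
        idx = int(np.searchsorted(self.frames, frame))
        if idx >= len(self.frames) or self.frames[idx] != frame:
            raise KeyError(f"frame {frame} not in trajectory")
        return idx
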