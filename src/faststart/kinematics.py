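"""Escape-performance measures from a tracked C-start trajectory.

Given CoM + snout tracks for one stimulation trial, this module extracts
the five standard fast-start performance measures

* response latency: stimulus-water contact to first head movement,
* escape distance D_esc: distance covered by the CoM in a fixed window
  (42 ms by default, the mean stage 1 + 2 duration in the reference study),
* maximum velocity U_max and maximum acceleration A_max within that window,
* stage-1 turning rate: stage-1 turning angle / stage-1 duration,

plus the stimulus covariates (initial orientation and distance to the
stimulus) and the stage-1 / stage-2 segmentation they depend on.  Speeds
and accelerations come from the five-point quadratic smoother applied to
the distance-time curve of the CoM; stage boundaries from the smoothed
angular velocity of the CoM-snout body segment.

Conventions: frames 0-based, lengths cm, times ms, speeds cm/s,
accelerations cm/s^2, angles degrees (counterclockwise-positive, y up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .smoothing import HALF_WINDOW, smooth_derivatives, smooth_values
from .trajectory import TrackedTrajectory

__all__ = [
    "AnalysisConfig",
    "KinematicSummary",
    "OnsetResult",
    "StageResult",
    "analyze_trial",
    "detect_onset_and_latency",
    "distance_time_maxima",
    "escape_distance",
    "heading_series",
    "mean_stage_window",
    "segment_stages",
    "stimulus_covariates",
    "turning_metrics",
]

MEASURES = ("latency_ms", "d_esc_cm", "u_max_cm_s", "a_max_cm_s2", "turning_rate_deg_ms")


@dataclass
class AnalysisConfig:
    """Tunable knobs of the per-trial analysis.

    The smoother is pinned to the five-point quadratic regression
    (window 5, order 2); only its application points are configurable.
    """

    window_ms: float = 42.0          # fixed distance-time analysis window
    onset_k: float = 5.0             # movement threshold, multiples of tracking noise
    onset_min_cm: float = 0.05       # absolute floor for the movement threshold
    non_mauthner_latency_ms: float = 200.0
    min_stage1_frames: int = 2
    d_esc_mode: str = "path"         # "path" (distance travelled) or "net" displacement
    deriv_method: str = "distance_time"  # "distance_time" (tangential) or "vector"
    stage2_decay_fraction: float = 0.10  # |omega| fraction of stage-1 peak = "straightened"

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.onset_k <= 0 or self.onset_min_cm <= 0:
            raise ValueError("onset thresholds must be positive")
        if self.d_esc_mode not in ("path", "net"):
            raise ValueError(f"unknown d_esc_mode {self.d_esc_mode!r}")
        if self.deriv_method not in ("distance_time", "vector"):
            raise ValueError(f"unknown deriv_method {self.deriv_method!r}")

    def window_frames(self, frame_rate_hz: float) -> int:
        """Window length as a whole number of frame intervals."""
        return int(round(self.window_ms * frame_rate_hz / 1000.0))


@dataclass
class OnsetResult:
    onset_frame: int | None
    latency_ms: float | None
    non_mauthner: bool
    flags: list[str] = field(default_factory=list)

    @property
    def responded(self) -> bool:
        return self.onset_frame is not None


@dataclass
class StageResult:
    stage1_end_frame: int | None
    stage2_end_frame: int | None
    flags: list[str] = field(default_factory=list)


@dataclass
class KinematicSummary:
    """Per-trial product of the pipeline; absent measures are None."""

    fish_id: str
    trial_number: int
    tl_cm: float
    latency_ms: float | None = None
    d_esc_cm: float | None = None
    u_max_cm_s: float | None = None
    a_max_cm_s2: float | None = None
    stage1_duration_ms: float | None = None
    stage2_end_ms: float | None = None
    turn_angle_deg: float | None = None
    turning_rate_deg_ms: float | None = None
    initial_orientation_deg: float | None = None
    initial_distance_cm: float | None = None
    non_mauthner_flag: bool = False
    quality_flags: list[str] = field(default_factory=list)

    @property
    def responded(self) -> bool:
        return "non_responsive" not in self.quality_flags


def heading_series(traj: TrackedTrajectory, fill_coincident: bool = True) -> np.ndarray:
    """Unwrapped heading (deg) of the CoM->snout body segment per frame.

    Frames where the two markers coincide have no defined heading; they are
    filled by holding the previous valid heading (``fill_coincident``) so
    the unwrap stays continuous.  If every frame is degenerate a ValueError
    is raised.
    """
    vec = traj.snout_xy_cm - traj.com_xy_cm
    norms = np.linalg.norm(vec, axis=1)
    bad = norms == 0.0
    if bad.all():
        raise ValueError("snout and CoM coincide on every frame; heading undefined")
    if bad.any() and not fill_coincident:
        raise ValueError(f"snout and CoM coincide on {int(bad.sum())} frame(s)")
    ang = np.arctan2(vec[:, 1], vec[:, 0])
    if bad.any():
        # hold last valid angle across degenerate frames before unwrapping
        idx = np.arange(len(ang))
        good_idx = idx[~bad]
        ang = np.interp(idx, good_idx, ang[~bad])
    return np.degrees(np.unwrap(ang))


def coincident_marker_frames(traj: TrackedTrajectory) -> np.ndarray:
    """Boolean mask of frames where snout and CoM coincide exactly."""
    return np.linalg.norm(traj.snout_xy_cm - traj.com_xy_cm, axis=1) == 0.0


def detect_onset_and_latency(traj: TrackedTrajectory, cfg: AnalysisConfig) -> OnsetResult:
    """Movement onset as a noise-adaptive snout-displacement threshold.

    The pre-stimulus frames provide a noise floor: sigma is the combined
    per-axis standard deviation of the snout position, and the movement
    threshold is max(onset_k * sigma, onset_min_cm).  The first
    post-stimulus frame whose displacement from the pre-stimulus median
    exceeds the threshold on two consecutive frames marks detection; the
    onset frame is then the last preceding quiet frame (displacement back
    at noise level), i.e. the frame at which the head starts to move.
    """
    si = traj.index_of_frame(traj.stimulus_frame)
    if si < 10:
        raise ValueError(f"need >= 10 pre-stimulus frames for the noise baseline, have {si}")
    pre = traj.snout_xy_cm[:si]
    med = np.median(pre, axis=0)
    sigma = float(np.sqrt(np.sum(np.var(pre, axis=0))))
    thresh = max(cfg.onset_k * sigma, cfg.onset_min_cm)
    quiet = max(2.5 * sigma, 0.5 * cfg.onset_min_cm)

    disp = np.linalg.norm(traj.snout_xy_cm - med, axis=1)
    n = traj.n_frames
    hit = None
    for i in range(si, n - 1):
        if disp[i] > thresh and disp[i + 1] > thresh:
            hit = i
            break
    if hit is None:
        return OnsetResult(None, None, False, flags=["non_responsive"])

    flags: list[str] = []
    onset_idx = si
    j = hit - 1
    while j >= si and disp[j] > quiet:
        j -= 1
    if j >= si:
        onset_idx = j
    else:
        flags.append("moving_at_stimulus")

    latency_ms = (traj.frames[onset_idx] - traj.stimulus_frame) * 1000.0 / traj.frame_rate_hz
    non_mauthner = latency_ms > cfg.non_mauthner_latency_ms
    return OnsetResult(int(traj.frames[onset_idx]), latency_ms, non_mauthner, flags)


def segment_stages(
    traj: TrackedTrajectory, onset_frame: int, cfg: AnalysisConfig
) -> StageResult:
    """Stage boundaries from the smoothed angular velocity of the heading.

    Stage 1 ends at the first reversal of the head's angular motion (first
    sign change of the smoothed angular velocity after the turn is under
    way); stage 2 ends at the next sign change or when |angular velocity|
    decays below ``stage2_decay_fraction`` of its stage-1 peak — a
    two-marker proxy for the body straightening.
    """
    onset_idx = traj.index_of_frame(onset_frame)
    si = traj.index_of_frame(traj.stimulus_frame)
    heading = heading_series(traj)
    omega, _ = smooth_derivatives(heading, traj.dt_s)  # deg/s

    pre = omega[HALF_WINDOW:si]
    sigma_w = float(np.nanstd(pre)) if len(pre) else 0.0
    arm = max(4.0 * sigma_w, 1e-9)

    n = traj.n_frames
    last = n - HALF_WINDOW  # exclusive; edge frames have no smoothed omega
    d = None
    for i in range(max(onset_idx, HALF_WINDOW), last):
        if abs(omega[i]) > arm:
            d = i
            break
    if d is None:
        return StageResult(None, None, flags=["no_rotation", "no_reversal"])
    sign0 = 1.0 if omega[d] > 0 else -1.0

    e = None
    for i in range(d + 1, last):
        if omega[i] * sign0 < 0:
            e = i
            break
    if e is None:
        return StageResult(None, None, flags=["no_reversal"])
    if e - onset_idx < cfg.min_stage1_frames:
        return StageResult(None, None, flags=["stage1_too_short"])
    peak1 = float(np.max(np.abs(omega[d:e])))

    s2 = None
    flags: list[str] = []
    armed2 = False
    for i in range(e + 1, last):
        if omega[i] * sign0 > 0:        # reversal back: double-bend completed
            s2 = i
            break
        a = abs(omega[i])
        if a >= cfg.stage2_decay_fraction * peak1:
            armed2 = True
        elif armed2:
            s2 = i
            break
    if s2 is None and not armed2 and e + 1 < last:
        s2 = e + 1                      # single-bend-like: rotation dies immediately
        flags.append("weak_stage2")
    if s2 is None:
        flags.append("no_stage2_end")
        return StageResult(int(traj.frames[e]), None, flags=flags)
    return StageResult(int(traj.frames[e]), int(traj.frames[s2]), flags=flags)


def _window_indices(
    traj: TrackedTrajectory, onset_frame: int, cfg: AnalysisConfig, margin: int
) -> tuple[int, int, list[str]]:
    """Array index range [onset, onset+n_int] and truncation flags.

    ``margin`` is the number of edge frames without smoothed output that
    the caller's estimator needs on each side.
    """
    onset_idx = traj.index_of_frame(onset_frame)
    n_int = cfg.window_frames(traj.frame_rate_hz)
    flags: list[str] = []
    end = onset_idx + n_int
    if end > traj.n_frames - 1 - margin:
        flags.append("truncated_window")
    return onset_idx, end, flags


def escape_distance(
    traj: TrackedTrajectory, onset_frame: int, cfg: AnalysisConfig
) -> tuple[float | None, list[str]]:
    """Distance covered by the (smoothed) CoM over the analysis window.

    Path length of the smoothed CoM polyline from the onset frame over
    round(window_ms * frame_rate) frame intervals; ``cfg.d_esc_mode="net"``
    returns the straight-line displacement instead.
    """
    onset_idx, end, flags = _window_indices(traj, onset_frame, cfg, HALF_WINDOW)
    if flags:
        return None, flags
    sm = smooth_values(traj.com_xy_cm)
    seg = sm[onset_idx : end + 1]
    if cfg.d_esc_mode == "net":
        return float(np.linalg.norm(seg[-1] - seg[0])), flags
    return float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1))), flags


def distance_time_maxima(
    traj: TrackedTrajectory, onset_frame: int, cfg: AnalysisConfig
) -> tuple[float | None, float | None, list[str]]:
    """Maximum smoothed speed and acceleration within the analysis window.

    Default method differentiates the cumulative distance-time curve of the
    smoothed CoM (speed = d(distance)/dt, acceleration = its derivative,
    i.e. the tangential component).  ``deriv_method="vector"`` instead
    differentiates x(t), y(t) separately and takes Euclidean norms, which
    additionally picks up the centripetal component during the turn.
    Maxima are taken over frames whose smoothing windows lie fully inside
    the recording.
    """
    onset_idx, end, flags = _window_indices(traj, onset_frame, cfg, HALF_WINDOW)
    if flags:
        return None, None, flags
    if cfg.deriv_method == "vector":
        vel, acc = smooth_derivatives(traj.com_xy_cm, traj.dt_s)
        speed = np.linalg.norm(vel, axis=1)
        accmag = np.linalg.norm(acc, axis=1)
    else:
        # the quadratic regression IS the smoothing: differentiate the raw
        # cumulative distance-time curve, as in the manual-tracking workflow
        steps = np.linalg.norm(np.diff(traj.com_xy_cm, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        speed, accel = smooth_derivatives(cum, traj.dt_s)
        accmag = np.abs(accel)
    win_s = speed[onset_idx : end + 1]
    win_a = accmag[onset_idx : end + 1]
    u_max = float(np.nanmax(win_s))
    a_max = float(np.nanmax(win_a))
    return u_max, a_max, flags


def _vector_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors, degrees in [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length vector has no direction")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def turning_metrics(
    traj: TrackedTrajectory, onset_frame: int, stage1_end_frame: int
) -> tuple[float, float]:
    """Stage-1 turning angle (deg) and turning rate (deg/ms).

    The turning angle is the angle between the CoM->snout segment at
    response start and the same segment at the end of stage 1 — the
    inter-vector angle in [0, 180], not the cumulative rotation.
    """
    i0 = traj.index_of_frame(onset_frame)
    i1 = traj.index_of_frame(stage1_end_frame)
    if i1 <= i0:
        raise ValueError("stage 1 must end after onset")
    v0 = traj.snout_xy_cm[i0] - traj.com_xy_cm[i0]
    v1 = traj.snout_xy_cm[i1] - traj.com_xy_cm[i1]
    angle = _vector_angle_deg(v0, v1)
    dur_ms = (i1 - i0) * 1000.0 / traj.frame_rate_hz
    return angle, angle / dur_ms


def stimulus_covariates(
    traj: TrackedTrajectory, onset_frame: int
) -> tuple[float, float]:
    """Initial orientation (deg, [0,180]) and distance (cm) to the stimulus.

    Orientation is the angle between the CoM->stimulus-edge and CoM->snout
    segments at response start.
    """
    i0 = traj.index_of_frame(onset_frame)
    com = traj.com_xy_cm[i0]
    to_stim = np.asarray(traj.stimulus_xy_cm, dtype=float) - com
    dist = float(np.linalg.norm(to_stim))
    if dist == 0.0:
        raise ValueError("CoM coincides with the stimulus point")
    to_snout = traj.snout_xy_cm[i0] - com
    return _vector_angle_deg(to_stim, to_snout), dist


def analyze_trial(traj: TrackedTrajectory, cfg: AnalysisConfig | None = None) -> KinematicSummary:
    """Full per-trial pipeline: onset -> stages -> window measures -> covariates.

    Partial failures set quality flags and leave the affected fields None
    instead of aborting the trial; only structurally invalid input raises.
    """
    cfg = cfg or AnalysisConfig()
    out = KinematicSummary(traj.fish_id, traj.trial_number, traj.tl_cm)
    if coincident_marker_frames(traj).any():
        out.quality_flags.append("coincident_markers")

    onset = detect_onset_and_latency(traj, cfg)
    out.quality_flags.extend(onset.flags)
    if not onset.responded:
        return out
    out.latency_ms = onset.latency_ms
    out.non_mauthner_flag = onset.non_mauthner

    try:
        out.initial_orientation_deg, out.initial_distance_cm = stimulus_covariates(
            traj, onset.onset_frame
        )
    except ValueError:
        out.quality_flags.append("degenerate_stimulus_geometry")

    out.d_esc_cm, dflags = escape_distance(traj, onset.onset_frame, cfg)
    out.u_max_cm_s, out.a_max_cm_s2, mflags = distance_time_maxima(
        traj, onset.onset_frame, cfg
    )
    out.quality_flags.extend(f for f in dflags + mflags if f not in out.quality_flags)

    stages = segment_stages(traj, onset.onset_frame, cfg)
    out.quality_flags.extend(f for f in stages.flags if f not in out.quality_flags)
    if stages.stage1_end_frame is not None:
        onset_idx = traj.index_of_frame(onset.onset_frame)
        s1_idx = traj.index_of_frame(stages.stage1_end_frame)
        out.stage1_duration_ms = (s1_idx - onset_idx) * 1000.0 / traj.frame_rate_hz
        out.turn_angle_deg, out.turning_rate_deg_ms = turning_metrics(
            traj, onset.onset_frame, stages.stage1_end_frame
        )
        if stages.stage2_end_frame is not None:
            s2_idx = traj.index_of_frame(stages.stage2_end_frame)
            out.stage2_end_ms = (s2_idx - onset_idx) * 1000.0 / traj.frame_rate_hz
    return out


def mean_stage_window(summaries: list[KinematicSummary]) -> float:
    """Mean stage 1 + 2 duration (ms) across trials.

    Offered as a data-driven alternative to the fixed 42 ms analysis
    window: the reference protocol set its window to this mean.
    """
    vals = [s.stage2_end_ms for s in summaries if s.stage2_end_ms is not None]
    if not vals:
        raise ValueError("no trial has both stage boundaries defined")
    return float(np.mean(vals))
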