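"""Delimited-text I/O for trajectories, measures tables and run configs.

All formats are plain text by design — tracking exports in this domain are
spreadsheets, and diffability beats compactness:

* trajectory CSV (one trial per file): header
  ``frame,t_s,com_x_cm,com_y_cm,snout_x_cm,snout_y_cm`` with a key-value
  YAML metadata sidecar ``<stem>.meta.yaml`` (fish_id, trial_number,
  tl_cm, frame_rate_hz, stimulus_frame, stimulus_x_cm, stimulus_y_cm,
  optionally scale_cm_per_px);
* generic point-track dialect ``frame,track_id,x_px,y_px`` (e.g. MTrackJ
  exports) converted via a declared track-id -> marker mapping and a
  pixel scale;
* long-format measures CSV:
  ``fish_id,trial,measure,value,tl_cm,initial_orientation_deg,
  initial_distance_cm,flag``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import MEASURES, KinematicSummary
from .simulate import GroundTruth
from .trajectory import TrackedTrajectory

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_measures",
    "write_measures",
    "summaries_to_table",
    "write_ground_truth",
    "read_ground_truth",
]

TRAJ_COLUMNS = ["frame", "t_s", "com_x_cm", "com_y_cm", "snout_x_cm", "snout_y_cm"]
TRACK_COLUMNS = ["frame", "track_id", "x_px", "y_px"]
MEASURE_COLUMNS = [
    "fish_id", "trial", "measure", "value",
    "tl_cm", "initial_orientation_deg", "initial_distance_cm", "flag",
]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_trajectory(traj: TrackedTrajectory, path: str | Path) -> Path:
    """Write a trial to the trajectory CSV dialect + metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "frame": traj.frames,
        "t_s": traj.time_s,
        "com_x_cm": traj.com_xy_cm[:, 0],
        "com_y_cm": traj.com_xy_cm[:, 1],
        "snout_x_cm": traj.snout_xy_cm[:, 0],
        "snout_y_cm": traj.snout_xy_cm[:, 1],
    })
    df.to_csv(path, index=False, float_format="%.9f")
    meta = {
        "fish_id": traj.fish_id,
        "trial_number": int(traj.trial_number),
        "tl_cm": float(traj.tl_cm),
        "frame_rate_hz": float(traj.frame_rate_hz),
        "stimulus_frame": int(traj.stimulus_frame),
        "stimulus_x_cm": float(traj.stimulus_xy_cm[0]),
        "stimulus_y_cm": float(traj.stimulus_xy_cm[1]),
    }
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def _read_meta(path: Path, overrides: dict | None) -> dict:
    mp = _meta_path(path)
    meta: dict = {}
    if mp.exists():
        meta = yaml.safe_load(mp.read_text()) or {}
    if overrides:
        meta.update(overrides)
    required = ["frame_rate_hz", "stimulus_frame", "stimulus_x_cm", "stimulus_y_cm"]
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"{path}: metadata sidecar missing keys {missing}")
    return meta


def read_trajectory(
    path: str | Path,
    meta: dict | None = None,
    track_map: dict[str, object] | None = None,
    scale_cm_per_px: float | None = None,
) -> TrackedTrajectory:
    """Read a trial from the native or the generic point-track dialect.

    Native files need the ``TRAJ_COLUMNS`` header; point-track files
    (``frame,track_id,x_px,y_px``) additionally need ``track_map``
    (e.g. ``{"com": 1, "snout": 2}``) and a pixel scale, either passed
    here or as ``scale_cm_per_px`` in the metadata sidecar.  Metadata
    comes from the sidecar, updated by the ``meta`` argument.

    Raises ValueError naming missing columns, duplicate frames or rows
    with unparseable values (by line number).
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    if set(TRAJ_COLUMNS) <= cols:
        sub = df[TRAJ_COLUMNS]
        bad = sub.index[sub.isna().any(axis=1)]
        if len(bad):
            raise ValueError(
                f"{path}: malformed rows at lines {[int(i) + 2 for i in bad]}"
            )
        m = _read_meta(path, meta)
        com = sub[["com_x_cm", "com_y_cm"]].to_numpy(float)
        snout = sub[["snout_x_cm", "snout_y_cm"]].to_numpy(float)
    elif set(TRACK_COLUMNS) <= cols:
        m = _read_meta(path, meta)
        track_map = track_map or m.get("track_map")
        scale = scale_cm_per_px if scale_cm_per_px is not None else m.get("scale_cm_per_px")
        if not track_map or scale is None:
            raise ValueError(
                f"{path}: point-track dialect needs track_map and scale_cm_per_px"
            )
        wide = {}
        for marker in ("com", "snout"):
            part = df[df["track_id"] == track_map[marker]].set_index("frame")
            wide[marker] = part[["x_px", "y_px"]].to_numpy(float) * float(scale)
            if marker == "com":
                frames = part.index.to_numpy()
            elif not np.array_equal(frames, part.index.to_numpy()):
                raise ValueError(f"{path}: com and snout tracks cover different frames")
        com, snout = wide["com"], wide["snout"]
        sub = pd.DataFrame({"frame": frames})
        sub["t_s"] = frames / float(m["frame_rate_hz"])
    else:
        missing = [c for c in TRAJ_COLUMNS if c not in cols]
        raise ValueError(f"{path}: missing required columns {missing}")

    frames = sub["frame"].to_numpy(int)
    if len(np.unique(frames)) != len(frames):
        dupes = pd.Series(frames).value_counts()
        raise ValueError(f"{path}: duplicate frames {list(dupes[dupes > 1].index)}")
    return TrackedTrajectory(
        frames=frames,
        time_s=sub["t_s"].to_numpy(float),
        com_xy_cm=com,
        snout_xy_cm=snout,
        frame_rate_hz=float(m["frame_rate_hz"]),
        stimulus_frame=int(m["stimulus_frame"]),
        stimulus_xy_cm=(float(m["stimulus_x_cm"]), float(m["stimulus_y_cm"])),
        fish_id=str(m.get("fish_id", path.stem)),
        trial_number=int(m.get("trial_number", 1)),
        tl_cm=float(m.get("tl_cm", np.nan)),
    )


def summaries_to_table(summaries: list[KinematicSummary]) -> pd.DataFrame:
    """Long-format measures table from per-trial summaries."""
    rows = []
    for s in summaries:
        flag = ";".join(s.quality_flags)
        for measure in MEASURES:
            rows.append({
                "fish_id": s.fish_id,
                "trial": s.trial_number,
                "measure": measure,
                "value": getattr(s, measure),
                "tl_cm": s.tl_cm,
                "initial_orientation_deg": s.initial_orientation_deg,
                "initial_distance_cm": s.initial_distance_cm,
                "flag": flag,
            })
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def write_measures(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.9f")
    return path


def read_measures(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format measures CSV, mapping external column names.

    ``column_map`` maps columns in the file to the native names, absorbing
    externally deposited table layouts.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("fish_id", "trial", "measure", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in MEASURE_COLUMNS:
        if c not in df.columns:
            df[c] = "" if c == "flag" else np.nan
    df["flag"] = df["flag"].fillna("")
    return df[MEASURE_COLUMNS]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth(**json.loads(Path(path).read_text()))


@dataclasses.dataclass
class RunConfig:
    """One file per run; command-line flags override these values."""

    frame_rate_hz: float = 240.0
    window_ms: float = 42.0
    onset_k: float = 5.0
    onset_min_cm: float = 0.05
    non_mauthner_latency_ms: float = 200.0
    d_esc_mode: str = "path"
    deriv_method: str = "distance_time"
    direction: str = "max"
    ci_method: str = "t"
    ddf_method: str = "within"
    seed: int = 0
    n_fish: int = 14
    n_trials: int = 5
    noise_sd_cm: float = 0.02
    among_cv: float = 0.30
    within_cv: float = 0.15
    scale_cm_per_px: float | None = None
    column_map: dict[str, str] | None = None

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def analysis_config(self):
        from .kinematics import AnalysisConfig

        return AnalysisConfig(
            window_ms=self.window_ms,
            onset_k=self.onset_k,
            onset_min_cm=self.onset_min_cm,
            non_mauthner_latency_ms=self.non_mauthner_latency_ms,
            d_esc_mode=self.d_esc_mode,
            deriv_method=self.deriv_method,
        )
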