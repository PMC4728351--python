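"""Five-point quadratic (Savitzky-Golay) smoothing of tracked coordinates.

Digitized trajectories carry tracking jitter that first and second finite
differences amplify badly at 240 Hz.  The standard remedy in fast-start
kinematics is a five-point quadratic polynomial regression: at each frame a
parabola is least-squares fitted to the centred five-frame window and its
value / first / second derivative at the window centre are taken as the
smoothed position, velocity and acceleration.  For a symmetric window the
fit reduces to fixed convolution weights, which is what this module applies.

Closed-form weights for window half-width 2, polynomial order 2:

* value:               (-3, 12, 17, 12, -3) / 35
* first derivative:    (-2, -1, 0, 1, 2) / (10 dt)
* second derivative:   (2, -1, -2, -1, 2) / (7 dt^2)

The estimates are exact for any polynomial of degree <= 2 (degree 3 as well
for the first derivative, by symmetry).  The first and last two frames have
no centred window and are returned as NaN; downstream maxima are taken over
fully covered frames only.
"""

from __future__ import annotations

import numpy as np

#: Number of frames on each side of the centre that the smoother consumes.
HALF_WINDOW = 2
WINDOW = 2 * HALF_WINDOW + 1

_W_VALUE = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0
_W_DERIV1 = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) / 10.0
_W_DERIV2 = np.array([2.0, -1.0, -2.0, -1.0, 2.0]) / 7.0


def _apply(series: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Correlate `weights` with `series` along axis 0; edges -> NaN."""
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] < WINDOW:
        raise ValueError(
            f"need at least {WINDOW} frames for the five-point smoother, "
            f"got {x.shape[0]}"
        )
    out = np.full_like(x, np.nan)
    core = sum(w * x[i : x.shape[0] - WINDOW + 1 + i] for i, w in enumerate(weights))
    out[HALF_WINDOW : x.shape[0] - HALF_WINDOW] = core
    return out[:, 0] if squeeze else out


def _check_dt(dt: float) -> float:
    dt = float(dt)
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError(f"frame interval dt must be positive and finite, got {dt}")
    return dt


def smooth_values(series: np.ndarray) -> np.ndarray:
    """Smoothed positions: the fitted parabola's value at each window centre.

    Accepts a 1-D series or an (n_frames, n_coords) array; the first and
    last two frames are NaN.
    """
    return _apply(series, _W_VALUE)


def smooth_derivatives(series: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """First and second time derivatives of a uniformly sampled series.

    Parameters
    ----------
    series
        1-D scalar series or (n_frames, n_coords) array sampled at a uniform
        interval ``dt`` (seconds).  Columns are smoothed independently.
    dt
        Frame interval in seconds.

    Returns
    -------
    (velocity, acceleration)
        Same shape as ``series``; NaN at the two edge frames on each end.

    Raises
    ------
    ValueError
        If fewer than five frames are supplied or ``dt`` is not positive.
    """
    dt = _check_dt(dt)
    vel = _apply(series, _W_DERIV1) / dt
    acc = _apply(series, _W_DERIV2) / (dt * dt)
    return vel, acc
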