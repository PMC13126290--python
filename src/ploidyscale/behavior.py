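"""Windowed swim metrics from tracked tadpole trajectories.

Speeds are finite-difference displacements assigned to the start of
each frame interval.  The "startle" window is the first second after
stimulation and the "cruising" window the last 60 s of the recording;
both are summarized by the geometric mean speed, the robust center for
right-skewed speed data, and group comparisons are run on log2 speeds.

The manual still / half-active / active scoring of the original assay
is replaced here by a thresholded surrogate: the fraction of frames
above a speed threshold, binned at 0.25 and 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SPEED_FLOOR = 1e-3  # mm/s, keeps geometric means defined for still frames


@dataclass
class SwimSummary:
    animal_id: str
    startle_speed: float        # mm/s, geometric mean over [0, 1) s
    cruising_speed: float       # mm/s, geometric mean over the last 60 s
    active_fraction: float
    first_half_active: bool
    activity_class: str         # {"still", "half_active", "active"}


def speeds(
    traj: pd.DataFrame,
    smooth_window: int = 0,
    max_gap_factor: float = 3.0,
) -> pd.DataFrame:
    """Instantaneous speed series (mm/s) for one animal's (t, x, y) samples.

    Frame gaps longer than ``max_gap_factor`` times the median interval
    break the differencing (no teleport speeds across dropped frames).
    Speeds are floored at a small epsilon so geometric averaging is
    defined for stationary animals.
    """
    t = traj["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    dx = np.diff(traj["x_mm"].to_numpy(dtype=float))
    dy = np.diff(traj["y_mm"].to_numpy(dtype=float))
    v = np.hypot(dx, dy) / dt
    ok = dt <= max_gap_factor * np.median(dt)
    t_out, v_out = t[:-1][ok], v[ok]
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        v_out = np.convolve(v_out, kernel, mode="same")
    v_out = np.maximum(v_out, SPEED_FLOOR)
    return pd.DataFrame({"t_s": t_out, "speed_mm_s": v_out})


def _geomean(v: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(v)))) if len(v) else np.nan


def window_speeds(
    traj: pd.DataFrame,
    startle_window: tuple[float, float] = (0.0, 1.0),
    cruise_seconds: float = 60.0,
    smooth_window: int = 0,
) -> tuple[float, float]:
    """Geometric-mean speed in the startle and cruising windows.

    Empty windows yield NaN (missing), never zero.
    """
    sp = speeds(traj, smooth_window=smooth_window)
    t = sp["t_s"].to_numpy()
    v = sp["speed_mm_s"].to_numpy()
    session_end = float(traj["t_s"].max())
    s0, s1 = startle_window
    startle = _geomean(v[(t >= s0) & (t < s1)])
    cruise = _geomean(v[t >= session_end - cruise_seconds])
    return startle, cruise


def classify_activity(
    traj: pd.DataFrame,
    speed_threshold: float = 1.0,
    bin_edges: tuple[float, float] = (0.25, 0.75),
    smooth_window: int = 0,
) -> tuple[str, float, bool]:
    """Thresholded surrogate for the manual activity scoring.

    Returns (activity_class, active_fraction, first_half_active); the
    first-half flag marks whether the majority of above-threshold frames
    fall in the first half of the session (meaningful for half-active
    animals that respond to the stimulus and then stop).
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    lo, hi = bin_edges
    sp = speeds(traj, smooth_window=smooth_window)
    active = sp["speed_mm_s"].to_numpy() > speed_threshold
    frac = float(active.mean())
    if frac < lo:
        cls = "still"
    elif frac < hi:
        cls = "half_active"
    else:
        cls = "active"
    t = sp["t_s"].to_numpy()
    mid = 0.5 * (t[0] + float(traj["t_s"].max()))
    n_active = active.sum()
    first_half = bool(active[t < mid].sum() > n_active / 2) if n_active else False
    return cls, frac, first_half


def summarize_animal(animal_id: str, traj: pd.DataFrame, **kwargs) -> SwimSummary:
    startle, cruise = window_speeds(traj)
    cls, frac, first_half = classify_activity(traj, **kwargs)
    return SwimSummary(
        animal_id=animal_id, startle_speed=startle, cruising_speed=cruise,
        active_fraction=frac, first_half_active=first_half, activity_class=cls,
    )


def summarize_session(traj: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-animal swim summaries for a multi-animal trajectory table."""
    rows = []
    for animal_id, grp in traj.groupby("animal_id", sort=True):
        s = summarize_animal(str(animal_id), grp.reset_index(drop=True), **kwargs)
        rows.append(s.__dict__)
    return pd.DataFrame(rows)


def compare_groups(speeds_a: np.ndarray, speeds_b: np.ndarray) -> dict:
    """Welch t-test of log2 speeds with geometric means per group."""
    la, lb = np.log2(speeds_a), np.log2(speeds_b)
    t, p = stats.ttest_ind(la, lb, equal_var=False)
    return dict(
        geomean_a=float(2 ** la.mean()), geomean_b=float(2 ** lb.mean()),
        t_stat=float(t), p_value=float(p),
    )


def repetition_trend(summaries: pd.DataFrame, mode: str = "startle") -> dict:
    """Linear trend of log2 speed across stimulation repetitions.

    ``summaries`` needs ``repetition`` and either ``startle_speed`` or
    ``cruising_speed`` columns; returns the OLS slope (log2 units per
    repetition) and its p-value.
    """
    import statsmodels.api as sm

    col = {"startle": "startle_speed", "cruise": "cruising_speed"}[mode]
    if summaries["repetition"].nunique() < 2:
        raise ValueError("need at least 2 repetitions")
    y = np.log2(summaries[col].to_numpy(dtype=float))
    x = sm.add_constant(summaries["repetition"].to_numpy(dtype=float))
    fit = sm.OLS(y, x).fit()
    return dict(slope=float(fit.params[1]), p_value=float(fit.pvalues[1]),
                intercept=float(fit.params[0]))
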