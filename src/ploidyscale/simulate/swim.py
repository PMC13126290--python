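"""Synthetic two-mode tadpole swim trajectories.

Tadpoles startle at stimulation and settle into a slower cruise: the
instantaneous speed is lognormal around ``startle_speed_mean`` for the
first ``startle_duration`` seconds and around ``cruise_speed_mean``
afterwards.  Heading follows a smooth random walk inside a square
arena (reflected at the walls).  A configurable fraction of animals
never moves at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SwimSimParams:
    n_animals: int = 6                 # per arena, as in one assay session
    startle_speed_mean: float = 20.0   # mm/s
    startle_duration: float = 1.0      # s
    cruise_speed_mean: float = 5.0     # mm/s
    speed_cv: float = 0.3
    frame_rate: float = 30.0           # Hz
    session_length: float = 120.0      # s, 2-min recording
    arena_size: float = 100.0          # mm
    heading_jitter: float = 0.6        # rad/frame sd
    still_fraction: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.session_length < 61.0:
            raise ValueError("session_length must be >= 61 s "
                             "(startle + cruising windows must both exist)")
        for name in ("startle_speed_mean", "cruise_speed_mean", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.still_fraction <= 1.0:
            raise ValueError("still_fraction must be in [0, 1]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


def _lognormal_speeds(rng, mean, cv, n):
    if cv <= 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2), n)


def simulate_trajectories(params: SwimSimParams, seed: int | None = None) -> pd.DataFrame:
    """Per-animal (t, x, y) samples with a truth_mode column per frame."""
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_frames = int(round(params.session_length * params.frame_rate)) + 1
    t = np.arange(n_frames) / params.frame_rate
    startle = t < params.startle_duration

    frames = []
    n_still = int(round(params.still_fraction * params.n_animals))
    for a in range(params.n_animals):
        is_still = a < n_still
        if is_still:
            x = np.full(n_frames, params.arena_size / 2)
            y = np.full(n_frames, params.arena_size / 2)
            mode = np.full(n_frames, "still")
        else:
            speeds = np.where(
                startle,
                _lognormal_speeds(rng, params.startle_speed_mean, params.speed_cv, n_frames),
                _lognormal_speeds(rng, params.cruise_speed_mean, params.speed_cv, n_frames),
            )
            heading = rng.uniform(0, 2 * np.pi) + np.cumsum(
                rng.normal(0.0, params.heading_jitter, n_frames)
            )
            # the speed drawn for frame i governs the segment [t_i, t_{i+1})
            step = speeds / params.frame_rate
            dx = np.cos(heading) * step
            dy = np.sin(heading) * step
            x = params.arena_size / 2 + np.concatenate([[0.0], np.cumsum(dx[:-1])])
            y = params.arena_size / 2 + np.concatenate([[0.0], np.cumsum(dy[:-1])])
            # reflect at the arena walls (keeps step lengths intact)
            for arr in (x, y):
                arr %= 2 * params.arena_size
                over = arr > params.arena_size
                arr[over] = 2 * params.arena_size - arr[over]
            mode = np.where(startle, "startle", "cruise")
        frames.append(pd.DataFrame({
            "animal_id": f"A{a + 1:02d}",
            "t_s": t, "x_mm": x, "y_mm": y,
            "truth_mode": mode,
            "truth_still": is_still,
        }))
    return pd.concat(frames, ignore_index=True)
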