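"""External drive: foraging trajectories, velocity and place/conjunctive input.

The arena is a 45 x 45 cm open field sampled at 50 Hz by default.  A
synthetic random-foraging generator (smooth heading random walk, speed
fluctuations around a mean, reflective walls) stands in for recorded
animal sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = [
    "Trajectory",
    "VelocitySignal",
    "PlaceFieldBank",
    "load_trajectory",
    "save_trajectory",
    "synthesize_trajectory",
    "velocity_from_trajectory",
    "conjunctive_drive",
    "place_drive",
]

ARENA_CM = 45.0
SPEED_CEILING = 90.0  # cm/s; faster samples are treated as tracking outliers


@dataclass
class Trajectory:
    """Timestamped 2-D positions: ``t`` in seconds, ``x``/``y`` in cm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_cm: float = ARENA_CM
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise FormatError("t, x, y must have equal lengths")
        if self.t.size == 0:
            raise FormatError("empty trajectory")
        if np.any(np.diff(self.t) <= 0):
            raise FormatError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def positions(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=1)

    def resample(self, dt_s: float) -> "Trajectory":
        """Linear interpolation to a uniform time base with step ``dt_s``."""
        if dt_s <= 0:
            raise ConfigurationError("resampling step must be positive")
        t_new = np.arange(self.t[0], self.t[-1] + 0.5 * dt_s, dt_s)
        return Trajectory(
            t=t_new,
            x=np.interp(t_new, self.t, self.x),
            y=np.interp(t_new, self.t, self.y),
            arena_cm=self.arena_cm,
        )

    def position_at(self, t_s: np.ndarray | float) -> np.ndarray:
        x = np.interp(t_s, self.t, self.x)
        y = np.interp(t_s, self.t, self.y)
        return np.stack(np.broadcast_arrays(x, y), axis=-1)


def load_trajectory(path, arena_cm: float = ARENA_CM) -> Trajectory:
    """Read a trajectory CSV with header columns t, x, y (s and cm).

    Out-of-arena samples are clipped into ``[0, arena_cm]``; the number of
    clipped samples is recorded on the result and reported as a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty trajectory file") from None
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty trajectory file")
    x = df["x"].to_numpy(dtype=np.float64)
    y = df["y"].to_numpy(dtype=np.float64)
    out = (x < 0) | (x > arena_cm) | (y < 0) | (y > arena_cm)
    n_clipped = int(out.sum())
    if n_clipped:
        warnings.warn(f"{path}: clipped {n_clipped} out-of-arena samples")
        x = np.clip(x, 0.0, arena_cm)
        y = np.clip(y, 0.0, arena_cm)
    return Trajectory(
        t=df["t"].to_numpy(dtype=np.float64), x=x, y=y,
        arena_cm=arena_cm, n_clipped=n_clipped,
    )


def save_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(path, index=False)


def synthesize_trajectory(
    duration_s: float,
    seed: int,
    mean_speed: float = 12.0,
    heading_persistence: float = 0.97,
    sample_rate_hz: float = 50.0,
    arena_cm: float = ARENA_CM,
) -> Trajectory:
    """Random-foraging surrogate trajectory.

    Heading performs a wrapped-Gaussian random walk whose increment SD is
    ``sqrt(2 (1 - heading_persistence))`` per sample; speed follows a
    mean-reverting fluctuation around ``mean_speed`` (floored at zero,
    capped at the outlier ceiling); walls reflect.  Fully reproducible
    from ``seed``.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration must be positive")
    if not 0.0 <= heading_persistence < 1.0:
        raise ConfigurationError("heading_persistence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    n = int(round(duration_s * sample_rate_hz)) + 1

    sigma_h = np.sqrt(2.0 * (1.0 - heading_persistence))
    heading = np.cumsum(rng.normal(0.0, sigma_h, size=n)) + rng.uniform(0, 2 * np.pi)

    # Mean-reverting speed fluctuation (AR(1)) around the configured mean.
    rho, sigma_s = 0.98, mean_speed / 3.0
    eps = rng.normal(0.0, sigma_s * np.sqrt(1 - rho**2), size=n)
    dev = np.empty(n)
    dev[0] = rng.normal(0.0, sigma_s)
    for i in range(1, n):
        dev[i] = rho * dev[i - 1] + eps[i]
    speed = np.clip(mean_speed + dev, 0.0, SPEED_CEILING)

    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = rng.uniform(0.3 * arena_cm, 0.7 * arena_cm, size=2)
    dx = np.cos(heading) * speed * dt
    dy = np.sin(heading) * speed * dt
    for i in range(1, n):
        xi = x[i - 1] + dx[i]
        yi = y[i - 1] + dy[i]
        # Reflective walls: fold position back and flip the heading
        # component for subsequent steps.
        if xi < 0 or xi > arena_cm:
            xi = np.clip(2 * np.clip(xi, 0, arena_cm) - xi, 0, arena_cm)
            dx[i:] = -dx[i:]
        if yi < 0 or yi > arena_cm:
            yi = np.clip(2 * np.clip(yi, 0, arena_cm) - yi, 0, arena_cm)
            dy[i:] = -dy[i:]
        x[i], y[i] = xi, yi
    t = np.arange(n) * dt
    return Trajectory(t=t, x=x, y=y, arena_cm=arena_cm)


@dataclass
class VelocitySignal:
    """Per-sample speed (cm/s) and heading (radians)."""

    t: np.ndarray
    speed: np.ndarray
    heading: np.ndarray

    def __len__(self) -> int:
        return self.t.size


def velocity_from_trajectory(
    traj: Trajectory,
    smoothing_window: int = 5,
    speed_ceiling: float = SPEED_CEILING,
) -> VelocitySignal:
    """Finite-difference velocity with boxcar smoothing and outlier capping.

    Heading is undefined at rest and carries the previous value forward.
    Speeds above ``speed_ceiling`` (default 90 cm/s, the tracking-outlier
    ceiling) are clipped.
    """
    if len(traj) < 2:
        raise ConfigurationError("velocity needs at least two trajectory samples")
    dt = np.diff(traj.t)
    vx = np.diff(traj.x) / dt
    vy = np.diff(traj.y) / dt
    # Sample i inherits the velocity of the step ending at i; first sample
    # duplicates the first step.
    vx = np.concatenate([[vx[0]], vx])
    vy = np.concatenate([[vy[0]], vy])
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        vx = np.convolve(np.pad(vx, pad, mode="edge"), kernel, mode="same")[pad:-pad]
        vy = np.convolve(np.pad(vy, pad, mode="edge"), kernel, mode="same")[pad:-pad]
    speed = np.hypot(vx, vy)
    over = speed > speed_ceiling
    if np.any(over):
        scale = speed_ceiling / speed[over]
        vx[over] *= scale
        vy[over] *= scale
        speed[over] = speed_ceiling
    heading = np.arctan2(vy, vx)
    # Heading is undefined at rest: carry the last moving heading forward.
    moving = speed > 1e-9
    idx = np.where(moving, np.arange(len(speed)), 0)
    np.maximum.accumulate(idx, out=idx)
    heading = heading[idx]
    return VelocitySignal(t=traj.t.copy(), speed=speed, heading=heading)


def conjunctive_drive(
    speed: np.ndarray | float,
    heading: np.ndarray | float,
    theta_pref: np.ndarray,
    I0: float,
    alpha: float,
) -> np.ndarray:
    """Speed-and-direction-tuned current for conjunctive cells (pA).

    I_i = I0 + alpha * speed * (1 + cos(heading - theta_i)) / 2.  The sum
    of the direction factor over the four cardinal preferences is 2 for
    any heading, so the population drive depends on speed only.
    """
    if I0 < 0 or alpha < 0:
        raise ConfigurationError("conjunctive gains must be non-negative")
    speed = np.asarray(speed, dtype=np.float64)
    heading = np.asarray(heading, dtype=np.float64)
    if speed.ndim:  # vectorized over time: result (T, N)
        tuning = 0.5 * (1.0 + np.cos(heading[:, None] - theta_pref[None, :]))
        return I0 + alpha * speed[:, None] * tuning
    tuning = 0.5 * (1.0 + np.cos(heading - theta_pref))
    return I0 + alpha * float(speed) * tuning


@dataclass
class PlaceFieldBank:
    """Gaussian place fields: one center per CA1 cell, shared width."""

    centers: np.ndarray  # (n, 2) cm
    sigma: float  # cm
    amplitude: float  # pA

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.sigma <= 0:
            raise ConfigurationError("place-field width must be positive")

    @classmethod
    def tile(
        cls, n_side: int, sigma: float, amplitude: float, arena_cm: float = ARENA_CM
    ) -> "PlaceFieldBank":
        """Field centers on an n_side x n_side lattice covering the arena."""
        step = arena_cm / n_side
        axis = (np.arange(n_side) + 0.5) * step
        gx, gy = np.meshgrid(axis, axis)
        centers = np.stack([gx.ravel(), gy.ravel()], axis=1)
        return cls(centers=centers, sigma=sigma, amplitude=amplitude)


def place_drive(position_cm: np.ndarray, bank: PlaceFieldBank) -> np.ndarray:
    """Gaussian place-field current per CA1 cell at the given position."""
    pos = np.asarray(position_cm, dtype=np.float64)
    d2 = np.sum((bank.centers - pos) ** 2, axis=1)
    return bank.amplitude * np.exp(-d2 / (2.0 * bank.sigma**2))
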