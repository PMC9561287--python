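"""Rendering of ground-truth trajectories into noisy two-channel traces.

The green channel reports the Cy3B/quencher pair on the ribosomal
subunits: unquenched high before 50S joining (and again after 50S
dissociation), low in the non-rotated state, medium in the rotated state,
and baseline after 70S dissociation or a green bleach.  The red channel
reports dye-labelled tRNA occupancy as 0, 1 or 2 unit levels.  Rendering
is piecewise-constant per trajectory interval plus additive zero-mean
Gaussian noise per frame; no camera model beyond that is attempted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .kinetics import (
    BLEACHED,
    DIS_50S,
    DIS_70S,
    MOVIE_LENGTH,
    NONROT,
    PIC,
    ROT,
    STALLED,
    CodonProgram,
    KineticPreset,
    Trajectory,
    default_program,
    sample_trajectory,
)

__all__ = ["EmissionConfig", "Trace", "render_trace", "simulate_dataset", "green_level_of"]


@dataclass(frozen=True)
class EmissionConfig:
    """Camera and dye parameters for rendering.

    Green levels must be ordered unquenched > rotated > non-rotated >
    baseline; the red channel is 0, 1 or 2 times ``red_unit``.  Defaults
    give roughly 6-17 noise-SDs of separation between adjacent levels.
    """

    frame_period: float = 0.1
    green_high: float = 1.0
    green_med: float = 0.45
    green_low: float = 0.15
    green_baseline: float = 0.0
    red_unit: float = 0.5
    noise_sd: float = 0.05
    movie_length: float = MOVIE_LENGTH

    def __post_init__(self) -> None:
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (self.green_high > self.green_med > self.green_low > self.green_baseline >= 0):
            raise ValueError("green levels must satisfy high > med > low > baseline >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_length / self.frame_period))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def green_level_of(cfg: EmissionConfig, state: str) -> float:
    """Ideal green intensity for a mechanistic state."""
    if state in (PIC, DIS_50S):
        return cfg.green_high
    if state in (NONROT, STALLED):
        return cfg.green_low
    if state == ROT:
        return cfg.green_med
    if state in (DIS_70S, BLEACHED):
        return cfg.green_baseline
    raise ValueError(f"unknown state {state!r}")


@dataclass
class Trace:
    """Sampled two-channel intensity time series for one molecule."""

    trace_id: str
    preset_id: str
    times: np.ndarray
    green: np.ndarray
    red: np.ndarray
    seed: int | None = None
    emission_hash: str = ""

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.green) == len(self.red)):
            raise ValueError("trace channel vectors must have equal length")
        if not (np.isfinite(self.green).all() and np.isfinite(self.red).all()):
            raise ValueError("trace intensities must be finite")


def render_trace(
    traj: Trajectory,
    cfg: EmissionConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Trace:
    """Render a trajectory into a noisy two-channel trace.

    Each frame takes the ideal level of the interval covering its
    timestamp; the red channel is the interval's dye count times the unit
    level, zeroed after the trajectory's red-bleach time.  Gaussian noise
    of SD ``cfg.noise_sd`` is then added independently per frame and
    channel (green first, then red, for a fixed draw order).
    """
    n = cfg.n_frames
    times = np.arange(n) * cfg.frame_period

    starts = np.array([iv.t_start for iv in traj.intervals])
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(traj.intervals) - 1)

    green_levels = np.array([green_level_of(cfg, iv.state) for iv in traj.intervals])
    red_counts = np.array([iv.cy5_count for iv in traj.intervals], dtype=float)
    green = green_levels[idx]
    red = red_counts[idx] * cfg.red_unit
    if traj.red_bleach_time is not None:
        red[times >= traj.red_bleach_time] = 0.0

    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        green = green + rng.normal(0.0, cfg.noise_sd, n)
        red = red + rng.normal(0.0, cfg.noise_sd, n)

    return Trace(
        trace_id=traj.trace_id,
        preset_id=traj.preset_id,
        times=times,
        green=green,
        red=red,
        seed=seed,
        emission_hash=cfg.config_hash(),
    )


def trace_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent per-trace stream derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, index)))


def simulate_dataset(
    n: int,
    preset: KineticPreset,
    cfg: EmissionConfig | None = None,
    seed: int = 0,
    program: CodonProgram | None = None,
) -> tuple[list[Trace], list[Trajectory]]:
    """Simulate ``n`` traces with paired ground truth.

    Per-trace randomness comes from a child stream of ``(seed, index)``,
    so the dataset is reproducible given ``(n, preset, cfg, seed)`` and
    individual traces can be regenerated in isolation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or EmissionConfig()
    program = program or default_program()
    traces: list[Trace] = []
    truths: list[Trajectory] = []
    for i in range(n):
        rng = trace_rng(seed, i)
        traj = sample_trajectory(program, preset, rng, trace_id=f"{preset.preset_id}:{i:06d}")
        trace = render_trace(traj, cfg, rng=rng, seed=seed)
        traces.append(trace)
        truths.append(traj)
    return traces, truths
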