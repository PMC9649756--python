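"""Synthetic granule dynamics: ground-truth schedules, traces and toy movies.

A granule's fluorescence content changes by discrete steps: nucleoprotein
complexes (one slncRNA plus its bound coat proteins) enter or are shed, each
carrying an intensity quantum ``K0`` scaled by a Poisson-distributed
occupancy.  Entry and shedding are emulated as independent Poisson processes
(exponential waiting times) on the ~10 minute scale observed for granule
dynamics.  Rendering adds a constant solution/cell background ``c0``, a
multiplicative single-exponential photobleaching factor ``f(t) = exp(-t/tau)``
and additive symmetric (Gaussian) noise on both the spot and background
channels, matching the noise model the downstream normalization assumes:

    y(t) = (S(t) + c0) * f(t) + eps,      c(t) = c0 * f(t) + eps'

The retained ground truth ``S_true`` is the oracle for recovery tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScheduledEvent",
    "GroundTruthSchedule",
    "TraceRenderConfig",
    "FrameStack",
    "PRESETS",
    "generate_burst_schedule",
    "render_trace",
    "render_movie",
]

ENTRY = "entry"
SHEDDING = "shedding"


@dataclass(frozen=True)
class ScheduledEvent:
    """One discrete content change: a complex (or several) enters or leaves."""

    time_s: float
    direction: str  # "entry" | "shedding"
    amplitude: float  # intensity units, > 0 regardless of direction

    def signed_amplitude(self) -> float:
        return self.amplitude if self.direction == ENTRY else -self.amplitude


@dataclass
class GroundTruthSchedule:
    """Latent event list for one granule plus the seed that produced it.

    ``initial_content`` is the granule fluorescence already present at t=0
    (shed events can only remove content that is there; an in-vitro granule
    starts loaded, an assembling one starts near zero).
    """

    events: list[ScheduledEvent]
    duration_s: float
    seed: int
    initial_content: float = 0.0

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(t < 0 or t > self.duration_s for t in times):
            raise ValueError("event times must lie within [0, duration]")
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if any(e.amplitude <= 0 for e in self.events):
            raise ValueError("event amplitudes must be > 0")

    def signal_at(self, times: np.ndarray) -> np.ndarray:
        """Running event sum (before clipping) evaluated at ``times``."""
        s = np.full(len(times), float(self.initial_content))
        for ev in self.events:
            s[times >= ev.time_s] += ev.signed_amplitude()
        return s


@dataclass
class TraceRenderConfig:
    """How a latent schedule is turned into an observed trace pair.

    c0 : constant underlying background intensity (A.U.); granule
        experiments typically show 350-450 A.U., default 400.
    bleach_timescale_s : photobleaching e-folding time tau; ``inf`` disables
        bleaching.
    noise_sd : additive Gaussian noise sd on each channel (A.U.).
    frame_interval_s / n_frames : default 10 s x 360 frames, i.e. a one hour
        acquisition at 6 frames per minute.
    """

    c0: float = 400.0
    bleach_timescale_s: float = math.inf
    noise_sd: float = 0.0
    frame_interval_s: float = 10.0
    n_frames: int = 360

    def __post_init__(self) -> None:
        if not (self.c0 >= 0):
            raise ValueError(f"c0 must be >= 0, got {self.c0}")
        if not (self.bleach_timescale_s > 0):
            raise ValueError(
                f"bleach_timescale_s must be > 0 (inf allowed), got {self.bleach_timescale_s}"
            )
        if not (self.noise_sd >= 0):
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (self.frame_interval_s > 0):
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def bleach(self, t: np.ndarray) -> np.ndarray:
        if math.isinf(self.bleach_timescale_s):
            return np.ones_like(np.asarray(t, dtype=float))
        return np.exp(-np.asarray(t, dtype=float) / self.bleach_timescale_s)


@dataclass
class FrameStack:
    """Image stack (t, row, col) with its frame interval."""

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a 3-D (t, row, col) array")
        if np.any(frames < 0):
            raise ValueError("frame intensities must be >= 0")
        self.frames = frames


# Condition presets.  "invitro-PCP14x" mimics degrading in-vitro granules of
# the longest hairpin cassette: shedding roughly every 10 min with rarer
# entries, occupancy lambda in the 2-3 range.  "invivo-balanced" mimics live
# cells where transcription balances degradation.
PRESETS: dict[str, dict] = {
    "invitro-PCP14x": dict(
        entry_rate_per_min=1.0 / 30.0,
        shedding_rate_per_min=0.1,  # mean inter-shedding 10 min
        amplitude_unit=100.0,
        occupancy=2.5,
        initial_content=2000.0,
        target_median_intershedding_s=600.0,
    ),
    "invivo-balanced": dict(
        entry_rate_per_min=0.1,
        shedding_rate_per_min=0.1,
        amplitude_unit=100.0,
        occupancy=1.0,
        initial_content=1000.0,
        target_median_intershedding_s=600.0,
    ),
}


def _check_finite_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value}")


def generate_burst_schedule(
    entry_rate_per_min: float,
    shedding_rate_per_min: float,
    amplitude_unit: float,
    occupancy: float,
    duration_s: float,
    seed: int,
    initial_content: float = 0.0,
) -> GroundTruthSchedule:
    """Draw a ground-truth event schedule for one granule.

    Entry and shedding events arrive as independent Poisson processes with
    the given rates (per minute).  Each event moves ``max(1, n)`` complexes,
    ``n ~ Poisson(occupancy)``, each worth ``amplitude_unit`` intensity units
    -- so every event moves at least one complex and the per-event amplitude
    distribution is the quantized one the modified-Poisson fit assumes.

    Parameters
    ----------
    entry_rate_per_min, shedding_rate_per_min:
        Event rates, events per minute; 0 disables that direction.
    amplitude_unit:
        Fluorescence of a single complex, K0 (> 0).
    occupancy:
        Poisson rate lambda for the number of complexes per event (>= 0).
    duration_s:
        Schedule length in seconds (> 0).
    seed:
        Seeds all randomness; identical inputs reproduce the schedule.
    """
    _check_finite_nonneg("entry_rate_per_min", entry_rate_per_min)
    _check_finite_nonneg("shedding_rate_per_min", shedding_rate_per_min)
    _check_finite_nonneg("occupancy", occupancy)
    _check_finite_nonneg("initial_content", initial_content)
    if not np.isfinite(amplitude_unit) or amplitude_unit <= 0:
        raise ValueError(f"amplitude_unit must be finite and > 0, got {amplitude_unit}")
    if not np.isfinite(duration_s) or duration_s <= 0:
        raise ValueError(f"duration_s must be finite and > 0, got {duration_s}")

    rng = np.random.default_rng(seed)
    events: list[ScheduledEvent] = []
    for direction, rate in ((ENTRY, entry_rate_per_min), (SHEDDING, shedding_rate_per_min)):
        if rate == 0:
            continue
        scale_s = 60.0 / rate  # mean waiting time in seconds
        t = rng.exponential(scale_s)
        while t <= duration_s:
            n = max(1, int(rng.poisson(occupancy)))
            events.append(ScheduledEvent(t, direction, amplitude_unit * n))
            t += rng.exponential(scale_s)
    events.sort(key=lambda e: e.time_s)
    return GroundTruthSchedule(
        events=events, duration_s=duration_s, seed=seed, initial_content=initial_content
    )


def schedule_from_preset(name: str, duration_s: float, seed: int) -> GroundTruthSchedule:
    """Generate a schedule from a named condition preset."""
    params = {k: v for k, v in PRESETS[name].items() if not k.startswith("target_")}
    return generate_burst_schedule(duration_s=duration_s, seed=seed, **params)


def render_trace(
    schedule: GroundTruthSchedule,
    config: TraceRenderConfig,
    seed: int,
    channel: str = "",
):
    """Render a schedule as an observed spot/background trace pair.

    Returns an :class:`~granuletrace.signals.IntensityTrace` whose ``s_true``
    field holds the injected (clipped) underlying signal.  Shedding past
    empty content is clipped at zero and the trace flagged.
    """
    from granuletrace.signals import IntensityTrace  # cycle-free at call time

    times = config.times
    window_end = times[-1]
    n_outside = sum(1 for e in schedule.events if e.time_s > window_end)
    if n_outside:
        warnings.warn(
            f"{n_outside} scheduled event(s) fall after the {window_end:.0f} s "
            "frame window and are ignored",
            stacklevel=2,
        )

    s_true = schedule.signal_at(times)
    clipped = bool(np.any(s_true < 0))
    if clipped:
        warnings.warn(
            "schedule sheds more content than present; underlying signal clipped at 0",
            stacklevel=2,
        )
        s_true = np.clip(s_true, 0.0, None)

    f = config.bleach(times)
    rng = np.random.default_rng(seed)
    eps_spot = rng.normal(0.0, config.noise_sd, size=len(times)) if config.noise_sd else 0.0
    eps_bg = rng.normal(0.0, config.noise_sd, size=len(times)) if config.noise_sd else 0.0
    y = (s_true + config.c0) * f + eps_spot
    c = config.c0 * f + eps_bg
    return IntensityTrace(
        time_s=times,
        y_raw=y,
        c_raw=c,
        channel=channel,
        s_true=s_true,
        clipped=clipped,
    )


def render_movie(
    schedules: list[GroundTruthSchedule],
    config: TraceRenderConfig,
    positions: list[tuple[float, float]],
    psf_sd: float,
    seed: int,
    shape: tuple[int, int] = (64, 64),
) -> FrameStack:
    """Render granules as isotropic Gaussian spots on a noisy background.

    Each granule at ``positions[i]`` (row, col) carries integrated intensity
    y(t) from its rendered noise-free trace; background pixels have mean
    c(t); per-pixel Gaussian noise of the configured sd is added on top.
    Spots must sit >= 7 px from every border so a 14-px sub-frame fits.
    """
    if psf_sd <= 0:
        raise ValueError(f"psf_sd must be > 0, got {psf_sd}")
    if len(schedules) != len(positions):
        raise ValueError("one position per schedule required")
    h, w = shape
    for r, c in positions:
        if r < 7 or c < 7 or r > h - 1 - 7 or c > w - 1 - 7:
            raise ValueError(f"position ({r}, {c}) is closer than 7 px to a border")

    noiseless = TraceRenderConfig(
        c0=config.c0,
        bleach_timescale_s=config.bleach_timescale_s,
        noise_sd=0.0,
        frame_interval_s=config.frame_interval_s,
        n_frames=config.n_frames,
    )
    times = noiseless.times
    bg = config.c0 * noiseless.bleach(times)

    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    kernels = []
    for r0, c0_pos in positions:
        k = np.exp(-((rr - r0) ** 2 + (cc - c0_pos) ** 2) / (2.0 * psf_sd**2))
        kernels.append(k / (2.0 * math.pi * psf_sd**2))

    rng = np.random.default_rng(seed)
    frames = np.empty((config.n_frames, h, w))
    traces = [render_trace(s, noiseless, seed=0) for s in schedules]
    for i in range(config.n_frames):
        frame = np.full((h, w), bg[i])
        for trace, kernel in zip(traces, kernels):
            # Gaussian integrates (over the infinite plane) to y(t_i)
            frame += trace.y_raw[i] * kernel
        if config.noise_sd:
            frame += rng.normal(0.0, config.noise_sd, size=(h, w))
        frames[i] = np.clip(frame, 0.0, None)
    return FrameStack(frames=frames, frame_interval_s=config.frame_interval_s)
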