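"""Seeded synthetic ECG generation with ground-truth R annotations.

Each beat is rendered as a sum of Gaussian bumps (P, Q, R, S, T) around the
beat's R time.  Stressors — a sinusoidal baseline-wander component, white
broadband noise and transient motion artifacts — can be layered on top
without touching the ground-truth annotations, which always describe the
clean beat process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .detector_core import EventSeries, InputError, UniformSignal

__all__ = [
    "Wave",
    "EcgModelParams",
    "WanderParams",
    "ArtifactParams",
    "DEFAULT_WAVES",
    "generate_ecg",
    "add_baseline_wander",
    "add_motion_artifact",
    "generate_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: amplitude (arb. units), center offset as a
    fraction of the beat period, and width (seconds, one sigma)."""

    amplitude: float
    offset: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InputError("wave width must be > 0")


# Default morphology: dominant R upstroke, QRS span < 100 ms at 60 bpm.
# The R width is chosen so the upstroke outlasts the detector's 20 ms
# refractory, letting the post-refractory re-capture reach the derivative
# maximum (a narrow spike would trap the threshold at the QRS onset value).
DEFAULT_WAVES: Dict[str, Wave] = {
    "P": Wave(0.12, -0.18, 0.025),
    "Q": Wave(-0.10, -0.035, 0.007),
    "R": Wave(1.00, 0.00, 0.011),
    "S": Wave(-0.20, 0.035, 0.007),
    "T": Wave(0.30, 0.32, 0.055),
}


@dataclass(frozen=True)
class EcgModelParams:
    """Generation parameters for one synthetic trace."""

    mean_hr: float = 60.0
    hr_variability: float = 0.0  # fractional STD of the beat period
    wave_set: Dict[str, Wave] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    noise_std: float = 0.0
    duration: float = 20.5
    sample_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_hr <= 0:
            raise InputError("mean_hr must be > 0")
        if self.hr_variability < 0 or self.noise_std < 0:
            raise InputError("hr_variability and noise_std must be >= 0")
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be > 0")
        if self.duration <= 2 * 60.0 / self.mean_hr:
            raise InputError("duration must cover more than two beats")
        r = self.wave_set.get("R")
        if r is None:
            raise InputError("wave_set must include an R wave")
        for name, w in self.wave_set.items():
            if name != "R" and w.amplitude >= r.amplitude:
                raise InputError("R must carry the largest positive amplitude")
        if r.amplitude <= 0:
            raise InputError("R amplitude must be positive")

    @classmethod
    def for_beats(cls, n_beats: int, **kwargs) -> "EcgModelParams":
        """Duration sized so a constant-rate trace holds exactly ``n_beats``."""
        mean_hr = kwargs.get("mean_hr", 60.0)
        period = 60.0 / mean_hr
        return cls(duration=(n_beats + 0.5) * period, **kwargs)

    def with_overrides(self, **kwargs) -> "EcgModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class WanderParams:
    """Sinusoidal baseline-wander component."""

    amplitude: float = 0.5
    frequency: float = 0.3
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InputError("wander amplitude must be >= 0")
        if self.frequency <= 0:
            raise InputError("wander frequency must be > 0")


@dataclass(frozen=True)
class ArtifactParams:
    """Transient motion artifacts: step offsets or high-frequency bursts."""

    event_times: Tuple[float, ...]
    amplitude: float
    duration: float
    shape: str = "step"  # or "burst"
    burst_frequency: float = 25.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InputError("artifact duration must be > 0")
        if self.shape not in ("step", "burst"):
            raise InputError(f"unknown artifact shape {self.shape!r}")


def _beat_times(params: EcgModelParams, rng: np.random.Generator) -> np.ndarray:
    period = 60.0 / params.mean_hr
    t0 = 0.5 * period
    horizon = params.duration - 0.5 * period
    times: List[float] = []
    t = t0
    floor = 0.021  # keep intervals above the detector refractory
    while t <= horizon + 1e-12:
        times.append(t)
        dt = period
        if params.hr_variability > 0:
            dt = rng.normal(period, params.hr_variability * period)
            dt = max(dt, floor)
        t += dt
    if len(times) < 2:
        raise InputError("parameters yield fewer than two beats")
    return np.asarray(times)


def generate_ecg(params: EcgModelParams) -> Tuple[UniformSignal, EventSeries]:
    """Render a synthetic trace and its exact R-peak annotations.

    Beat periods are drawn from a truncated normal (mean ``60/mean_hr``,
    STD ``hr_variability`` times the mean).  Beat and noise randomness use
    independent child streams of ``seed`` so that scaling ``noise_std``
    rescales the very same noise pattern.
    """
    seq = np.random.SeedSequence(params.seed)
    beat_rng, noise_rng = (np.random.default_rng(s) for s in seq.spawn(2))
    beats = _beat_times(params, beat_rng)
    n = int(round(params.duration * params.sample_rate)) + 1
    t = np.arange(n) / params.sample_rate
    y = np.zeros(n)
    period = 60.0 / params.mean_hr
    for b in beats:
        for wave in params.wave_set.values():
            c = b + wave.offset * period
            lo = np.searchsorted(t, c - 5 * wave.width)
            hi = np.searchsorted(t, c + 5 * wave.width)
            if lo >= hi:
                continue
            seg = t[lo:hi] - c
            y[lo:hi] += wave.amplitude * np.exp(-(seg**2) / (2 * wave.width**2))
    if params.noise_std > 0:
        y = y + params.noise_std * noise_rng.standard_normal(n)
    sig = UniformSignal(0.0, 1.0 / params.sample_rate, y)
    truth = EventSeries("r_wave_truth", beats)
    return sig, truth


def add_baseline_wander(sig: UniformSignal, w: WanderParams) -> UniformSignal:
    """Pointwise sum with ``amplitude * sin(2*pi*frequency*t + phase)``."""
    t = sig.times()
    wander = w.amplitude * np.sin(2 * math.pi * w.frequency * t + w.phase)
    return UniformSignal(sig.start_time, sig.sample_interval, sig.samples + wander)


def add_motion_artifact(sig: UniformSignal, a: ArtifactParams) -> UniformSignal:
    """Superpose step offsets or sinusoidal bursts at the given event times."""
    t = sig.times()
    y = sig.samples.copy()
    for e in a.event_times:
        if e < sig.start_time or e > sig.end_time:
            raise InputError(f"artifact event at {e} s lies outside the trace span")
        mask = (t >= e) & (t < e + a.duration)
        if a.shape == "step":
            y[mask] += a.amplitude
        else:
            y[mask] += a.amplitude * np.sin(
                2 * math.pi * a.burst_frequency * (t[mask] - e)
            )
    return UniformSignal(sig.start_time, sig.sample_interval, y)


# ---------------------------------------------------------------------------
# named fixture presets
# ---------------------------------------------------------------------------

PRESETS = ("clean", "wander", "noisy", "motion")


def generate_preset(
    name: str,
    seed: int = 0,
    n_beats: int = 20,
    mean_hr: float = 60.0,
    noise_std: float = 0.03,
) -> Tuple[UniformSignal, EventSeries]:
    """One-call fixture sets used by tests and the CLI.

    clean   — noiseless constant-rate morphology only
    wander  — clean plus a 0.5*R, 0.3 Hz sinusoidal baseline wander
    noisy   — wander plus broadband noise
    motion  — wander plus two step artifacts mid-trace
    """
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; choose from {PRESETS}")
    params = EcgModelParams.for_beats(n_beats, mean_hr=mean_hr, seed=seed)
    if name == "noisy":
        params = params.with_overrides(noise_std=noise_std)
    sig, truth = generate_ecg(params)
    if name in ("wander", "noisy", "motion"):
        r_amp = params.wave_set["R"].amplitude
        sig = add_baseline_wander(sig, WanderParams(0.5 * r_amp, 0.3, 0.0))
    if name == "motion":
        dur = sig.duration
        events = (0.35 * dur, 0.7 * dur)
        sig = add_motion_artifact(
            sig, ArtifactParams(events, amplitude=0.4, duration=0.25, shape="step")
        )
    return sig, truth
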