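"""Tick-driven ECG-to-TTL trigger engine.

The detector walks a uniformly resampled ECG trace one tick at a time,
estimating the signal derivative with a two-point finite difference and
comparing it against an adaptively decaying threshold.  Each threshold
crossing outside the refractory window counts as an R-wave detection,
re-arms the threshold at the crossing value, updates the running beat
period, and schedules the next TTL rising edge one period ahead (minus a
configurable phase offset).  The TTL line is dropped low again once the
pulse has been high for at least ``pulse_width`` seconds.

Two interchangeable drivers are provided:

* :func:`run_streaming` — folds :func:`step` over the trace, one tick at a
  time, exactly as a microcontroller loop would.
* :func:`run_batch` — an independent whole-array reference implementation
  used as an oracle; it must produce bit-identical TTL output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "TTL_LOW",
    "TTL_HIGH",
    "UniformSignal",
    "EventSeries",
    "DetectorConfig",
    "DetectorState",
    "StreamResult",
    "DetectorError",
    "BoundaryError",
    "AlignmentError",
    "OrderingError",
    "StateCorruptionError",
    "InputError",
    "finite_difference",
    "decay_threshold",
    "update_heart_rate",
    "schedule_trigger",
    "step",
    "run_streaming",
    "run_batch",
    "resample_to_grid",
]

logger = logging.getLogger(__name__)

TTL_LOW = 0
TTL_HIGH = 1

#: Floor applied when the threshold is seeded from the first difference so
#: that the thr > 0 invariant holds even on a flat lead-in.
THRESHOLD_FLOOR = 1e-9

FIRST_ORDER = "first_order"
TRUE_EXPONENTIAL = "true_exponential"
_DECAY_LAWS = (FIRST_ORDER, TRUE_EXPONENTIAL)

_WARMUP_POLICIES = ("suppress_until_two_detections",)


class DetectorError(Exception):
    """Base class for detector failures."""


class BoundaryError(DetectorError, ValueError):
    """Requested time falls outside the usable span of the signal."""


class AlignmentError(DetectorError, ValueError):
    """Requested time is not on the tick grid."""


class OrderingError(DetectorError, ValueError):
    """Event times are not strictly increasing."""


class StateCorruptionError(DetectorError, RuntimeError):
    """Internal state violates an invariant (e.g. non-positive threshold)."""


class InputError(DetectorError, ValueError):
    """Malformed or too-short input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled scalar time series.

    Sample ``k`` (0-based) is taken at ``start_time + k * sample_interval``.
    Amplitudes are in arbitrary units for ECG traces; TTL traces carry only
    the two logic levels 0 and 1.
    """

    start_time: float
    sample_interval: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_interval <= 0:
            raise InputError("sample_interval must be > 0")
        if samples.ndim != 1 or samples.size < 2:
            raise InputError("a signal needs at least 2 samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def end_time(self) -> float:
        return self.start_time + (len(self) - 1) * self.sample_interval

    @property
    def duration(self) -> float:
        return (len(self) - 1) * self.sample_interval

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) * self.sample_interval

    def is_ttl(self) -> bool:
        """True when the trace holds only the two logic levels."""
        return bool(np.isin(self.samples, (float(TTL_LOW), float(TTL_HIGH))).all())

    def level_at(self, t: float) -> int:
        """Logic level at time ``t`` (nearest sample)."""
        k = int(round((t - self.start_time) / self.sample_interval))
        if k < 0 or k >= len(self):
            raise BoundaryError(f"time {t} outside signal span")
        return TTL_HIGH if self.samples[k] > 0.5 else TTL_LOW


@dataclass(frozen=True)
class EventSeries:
    """Annotated time points of one kind (truth R-waves, detections, edges)."""

    kind: str
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise InputError("event times must be one-dimensional")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise OrderingError(f"{self.kind} event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DetectorConfig:
    """All algorithm constants.

    Defaults mirror the reference device: 5 ms tick, decay rate 0.0014,
    20 ms refractory, 25 ms pulse, zero phase offset.
    """

    tick: float = 0.005
    decay_rate: float = 0.0014
    refractory: float = 0.020
    pulse_width: float = 0.025
    dt_mp: float = 0.0
    decay_law: str = FIRST_ORDER
    warmup_policy: str = "suppress_until_two_detections"
    #: optional plausibility clamp on the period estimate, off by default
    min_hr: Optional[float] = None
    max_hr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tick <= 0:
            raise InputError("tick must be > 0")
        if not 0.0 < self.decay_rate < 1.0:
            raise InputError("decay_rate must lie in (0, 1)")
        if self.refractory < 0 or self.pulse_width < 0 or self.dt_mp < 0:
            raise InputError("refractory, pulse_width and dt_mp must be >= 0")
        if self.decay_law not in _DECAY_LAWS:
            raise InputError(f"unknown decay_law {self.decay_law!r}")
        if self.warmup_policy not in _WARMUP_POLICIES:
            raise InputError(f"unknown warmup_policy {self.warmup_policy!r}")
        if (
            self.min_hr is not None
            and self.max_hr is not None
            and self.min_hr > self.max_hr
        ):
            raise InputError("min_hr must not exceed max_hr")

    # smallest integer tick gap strictly exceeding the refractory interval
    @property
    def min_gap_ticks(self) -> int:
        return int(math.floor(self.refractory / self.tick + 1e-9)) + 1

    # smallest tick count spanning at least one pulse width (>= 1 so that a
    # raise always yields a visible pulse; lowering waits for the next tick)
    @property
    def pulse_ticks(self) -> int:
        return max(1, int(math.ceil(self.pulse_width / self.tick - 1e-9)))

    def with_overrides(self, **kwargs) -> "DetectorConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DetectorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class DetectorState:
    """Live algorithm state, advanced one tick at a time by :func:`step`."""

    thr: Optional[float] = None
    last_detection_time: Optional[float] = None
    period_estimate: Optional[float] = None
    heart_rate: Optional[float] = None
    ttl_level: int = TTL_LOW
    pulse_raised_at: Optional[float] = None
    detections_seen: int = 0
    pending_raises: List[float] = field(default_factory=list)

    def check(self) -> None:
        if self.thr is not None and self.thr <= 0:
            raise StateCorruptionError("threshold must stay positive")
        if self.ttl_level == TTL_HIGH and self.pulse_raised_at is None:
            raise StateCorruptionError("high TTL without a recorded raise time")


@dataclass(frozen=True)
class StreamResult:
    """Everything one detector run produces."""

    ttl: UniformSignal
    detections: EventSeries
    rising: EventSeries
    falling: EventSeries
    hr_series: List[Tuple[float, float]]
    threshold: np.ndarray
    grid: UniformSignal


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _grid_index(sig: UniformSignal, t: float, cfg: DetectorConfig) -> int:
    q = (t - sig.start_time) / cfg.tick
    k = int(round(q))
    if abs(q - k) > 1e-6:
        raise AlignmentError(f"time {t} is not on the tick grid")
    return k


def finite_difference(ecg: UniformSignal, t: float, cfg: DetectorConfig) -> float:
    """Two-point difference ``ecg(t + tick) - ecg(t)``.

    The value is deliberately not divided by the tick; the threshold units
    absorb that factor.  ``ecg`` must already be on the tick grid.
    """
    if abs(ecg.sample_interval - cfg.tick) > 1e-9 * max(1.0, cfg.tick):
        raise AlignmentError("signal is not sampled on the tick grid")
    k = _grid_index(ecg, t, cfg)
    if k < 0 or k + 1 >= len(ecg):
        raise BoundaryError(f"t={t} and t+tick must both lie inside the signal span")
    return float(ecg.samples[k + 1] - ecg.samples[k])


def decay_threshold(thr: float, cfg: DetectorConfig) -> float:
    """One tick of threshold decay.

    ``first_order`` multiplies by ``(1 - x)``; ``true_exponential`` applies
    ``thr * exp(-thr * x)`` (the exponent intentionally carries thr; see
    README notes on the exponential variant).
    """
    if thr is None or thr <= 0:
        raise StateCorruptionError("cannot decay a non-positive threshold")
    if cfg.decay_law == FIRST_ORDER:
        return thr * (1.0 - cfg.decay_rate)
    return thr * math.exp(-thr * cfg.decay_rate)


def update_heart_rate(ti: float, ti_prev: float) -> Tuple[float, float]:
    """Beat period and heart rate from two consecutive detection times."""
    if ti <= ti_prev:
        raise OrderingError("detection times must be strictly increasing")
    tj = ti - ti_prev
    return tj, 60.0 / tj


def schedule_trigger(ti: float, tj: float, cfg: DetectorConfig) -> float:
    """Earliest tick-grid time strictly after ``ti + (Tj - dt_mp)``.

    When ``dt_mp >= Tj`` the request is unsatisfiable and the trigger is
    clamped to the next tick after ``ti`` (with a warning).
    """
    if tj is None or tj <= 0:
        raise InputError("a positive period estimate is required to schedule")
    if cfg.dt_mp >= tj:
        logger.warning(
            "dt_mp (%.4f s) >= period estimate (%.4f s); clamping trigger to the next tick",
            cfg.dt_mp,
            tj,
        )
        return ti + cfg.tick
    q = (tj - cfg.dt_mp) / cfg.tick
    qr = round(q)
    m = int(qr) + 1 if abs(q - qr) <= 1e-6 else int(math.ceil(q))
    return ti + m * cfg.tick


# ---------------------------------------------------------------------------
# streaming engine
# ---------------------------------------------------------------------------


def step(
    state: DetectorState,
    ecg: UniformSignal,
    t: float,
    cfg: DetectorConfig,
) -> Tuple[DetectorState, int, List[Tuple[str, float]]]:
    """Advance the detector by exactly one tick at grid time ``t``.

    Mutates and returns ``state`` together with the TTL output level for the
    tick and the events emitted during it (``r_detection``, ``ttl_rising``,
    ``ttl_falling``, ``hr_update``).
    """
    k = _grid_index(ecg, t, cfg)
    if k < 0 or k + 1 >= len(ecg):
        raise BoundaryError("tick runs past the end of the trace")
    events: List[Tuple[str, float]] = []
    half = 0.5 * cfg.tick
    raised_now = False

    # 1. fire any due scheduled raise; a raise arriving while the line is
    # still high is dropped (the stuck-high failure mode), as is any raise
    # before the warm-up policy is satisfied.
    if state.pending_raises:
        due = [p for p in state.pending_raises if p <= t + half]
        if due:
            state.pending_raises = [p for p in state.pending_raises if p > t + half]
            if state.ttl_level == TTL_LOW and state.detections_seen >= 2:
                state.ttl_level = TTL_HIGH
                state.pulse_raised_at = t
                raised_now = True
                events.append(("ttl_rising", t))

    # 2. lower the line once the pulse has been high long enough; a raise in
    # the same tick wins and the lowering waits for the next tick.
    if (
        state.ttl_level == TTL_HIGH
        and not raised_now
        and (t - state.pulse_raised_at) >= cfg.pulse_width - 1e-9 * max(1.0, cfg.pulse_width)
    ):
        state.ttl_level = TTL_LOW
        state.pulse_raised_at = None
        events.append(("ttl_falling", t))

    # 3. derivative estimate and threshold comparison.
    d = float(ecg.samples[k + 1] - ecg.samples[k])
    if state.thr is None:
        # no online rule exists for the very first threshold; seed it from
        # the first tick's difference magnitude and let re-captures dominate
        state.thr = max(abs(d), THRESHOLD_FLOOR)
    if state.last_detection_time is None:
        gap_ok = True
    else:
        gap_ticks = int(round((t - state.last_detection_time) / cfg.tick))
        gap_ok = gap_ticks >= cfg.min_gap_ticks
    if d > state.thr and gap_ok:
        events.append(("r_detection", t))
        if state.last_detection_time is not None:
            tj, hr = update_heart_rate(t, state.last_detection_time)
            accept = True
            if cfg.min_hr is not None and hr < cfg.min_hr:
                accept = False
            if cfg.max_hr is not None and hr > cfg.max_hr:
                accept = False
            if accept:
                state.period_estimate = tj
                state.heart_rate = hr
                events.append(("hr_update", t))
        if state.period_estimate is not None:
            state.pending_raises.append(
                schedule_trigger(t, state.period_estimate, cfg)
            )
        state.thr = max(d, THRESHOLD_FLOOR)
        state.last_detection_time = t
        state.detections_seen += 1
    else:
        state.thr = decay_threshold(state.thr, cfg)

    state.check()
    output = state.ttl_level if state.detections_seen >= 2 else TTL_LOW
    return state, output, events


def resample_to_grid(ecg: UniformSignal, cfg: DetectorConfig) -> UniformSignal:
    """Linearly interpolate a trace onto the detector's tick grid."""
    if abs(ecg.sample_interval - cfg.tick) <= 1e-9 * max(1.0, cfg.tick):
        return ecg
    n_ticks = int(math.floor(ecg.duration / cfg.tick + 1e-9))
    if n_ticks < 1:
        raise InputError("trace is shorter than one tick")
    grid_times = ecg.start_time + np.arange(n_ticks + 1) * cfg.tick
    samples = np.interp(grid_times, ecg.times(), ecg.samples)
    return UniformSignal(ecg.start_time, cfg.tick, samples)


def run_streaming(ecg: UniformSignal, cfg: DetectorConfig) -> StreamResult:
    """Fold :func:`step` over a whole trace.

    The trace is first resampled to the tick grid.  Returns the TTL output
    (one sample per tick, the last tick's level replicated to the final
    sample), detection and edge event series, the heart-rate updates and the
    per-tick threshold trace.
    """
    grid = resample_to_grid(ecg, cfg)
    n = len(grid)
    if n < 3:
        raise InputError("trace must span more than two ticks")
    state = DetectorState()
    ttl = np.zeros(n, dtype=float)
    thr_trace = np.empty(n - 1, dtype=float)
    det_times: List[float] = []
    rise_times: List[float] = []
    fall_times: List[float] = []
    hr_series: List[Tuple[float, float]] = []
    for k in range(n - 1):
        t = grid.start_time + k * cfg.tick
        _, out, events = step(state, grid, t, cfg)
        ttl[k] = out
        thr_trace[k] = state.thr
        for kind, when in events:
            if kind == "r_detection":
                det_times.append(when)
            elif kind == "ttl_rising":
                rise_times.append(when)
            elif kind == "ttl_falling":
                fall_times.append(when)
            elif kind == "hr_update":
                hr_series.append((when, state.heart_rate))
    ttl[n - 1] = ttl[n - 2]
    return StreamResult(
        ttl=UniformSignal(grid.start_time, cfg.tick, ttl),
        detections=EventSeries("r_detection", np.asarray(det_times)),
        rising=EventSeries("ttl_rising", np.asarray(rise_times)),
        falling=EventSeries("ttl_falling", np.asarray(fall_times)),
        hr_series=hr_series,
        threshold=thr_trace,
        grid=grid,
    )


# ---------------------------------------------------------------------------
# batch reference implementation (oracle)
# ---------------------------------------------------------------------------


def _batch_detect_first_order(d: np.ndarray, cfg: DetectorConfig) -> List[int]:
    # Between resets the threshold follows the closed form
    #   thr(compare at tick k) = thr0 * (1 - x)^(k - k0 - 1)
    # with the seed acting as a reset at virtual tick -1.  Scanning segment
    # by segment in log space avoids replaying the per-tick decay.
    nt = d.size
    lam = math.log1p(-cfg.decay_rate)
    logd = np.full(nt, -np.inf)
    pos = d > 0
    logd[pos] = np.log(d[pos])
    thr0 = max(abs(float(d[0])), THRESHOLD_FLOOR)
    k0 = -1
    last: Optional[int] = None
    dets: List[int] = []
    start = 1
    while start < nt:
        lo = start if last is None else max(start, last + cfg.min_gap_ticks)
        if lo >= nt:
            break
        ks = np.arange(lo, nt)
        ok = logd[lo:] > math.log(thr0) + (ks - k0 - 1) * lam
        j = int(np.argmax(ok))
        if not ok[j]:
            break
        kd = lo + j
        dets.append(kd)
        thr0 = float(d[kd])
        k0 = kd
        last = kd
        start = kd + 1
    return dets


def _batch_detect_true_exponential(d: np.ndarray, cfg: DetectorConfig) -> List[int]:
    # no closed form for the printed exponential law; replay per tick
    thr = max(abs(float(d[0])), THRESHOLD_FLOOR)
    thr *= math.exp(-thr * cfg.decay_rate)  # tick 0 never detects, only decays
    last: Optional[int] = None
    dets: List[int] = []
    for k in range(1, d.size):
        dk = float(d[k])
        if dk > thr and (last is None or k - last >= cfg.min_gap_ticks):
            dets.append(k)
            thr = dk
            last = k
        else:
            thr *= math.exp(-thr * cfg.decay_rate)
    return dets


def run_batch(ecg: UniformSignal, cfg: DetectorConfig) -> StreamResult:
    """Whole-array reference implementation.

    Independent of :func:`step`; detection uses the closed-form decay per
    segment and the TTL pulse train is rebuilt from the detection list.
    Must match :func:`run_streaming` sample for sample.
    """
    grid = resample_to_grid(ecg, cfg)
    n = len(grid)
    if n < 3:
        raise InputError("trace must span more than two ticks")
    d = np.diff(grid.samples)
    if cfg.decay_law == FIRST_ORDER:
        dets = _batch_detect_first_order(d, cfg)
    else:
        dets = _batch_detect_true_exponential(d, cfg)

    # rebuild heart-rate updates and scheduled raises
    hr_series: List[Tuple[float, float]] = []
    pend: List[int] = []
    t_of = lambda k: grid.start_time + k * cfg.tick  # noqa: E731
    tj_current: Optional[float] = None
    for j, kd in enumerate(dets):
        if j >= 1:
            tj = (kd - dets[j - 1]) * cfg.tick
            hr = 60.0 / tj
            accept = True
            if cfg.min_hr is not None and hr < cfg.min_hr:
                accept = False
            if cfg.max_hr is not None and hr > cfg.max_hr:
                accept = False
            if accept:
                tj_current = tj
                hr_series.append((t_of(kd), hr))
        if tj_current is not None:
            raise_t = schedule_trigger(t_of(kd), tj_current, cfg)
            pend.append(int(round((raise_t - grid.start_time) / cfg.tick)))
    pend.sort()

    # pulse train: a due raise fires only if the line is low when the tick
    # is entered (the lowering tick itself still reads high)
    nt = n - 1
    pw = cfg.pulse_ticks
    rising: List[int] = []
    falling: List[int] = []
    lower_at = -(10**18)
    for r in pend:
        if r <= lower_at or r >= nt:
            continue
        rising.append(r)
        lower_at = r + pw
        if lower_at <= nt - 1:
            falling.append(lower_at)
    ttl = np.zeros(n, dtype=float)
    for i, r in enumerate(rising):
        end = min(r + pw, nt)
        ttl[r:end] = 1.0
    ttl[n - 1] = ttl[n - 2]

    # per-tick threshold trace, replayed with the closed form for parity
    thr_trace = np.empty(nt, dtype=float)
    thr = max(abs(float(d[0])), THRESHOLD_FLOOR)
    det_set = set(dets)
    for k in range(nt):
        if k in det_set:
            thr = max(float(d[k]), THRESHOLD_FLOOR)
        else:
            thr = decay_threshold(thr, cfg)
        thr_trace[k] = thr

    return StreamResult(
        ttl=UniformSignal(grid.start_time, cfg.tick, ttl),
        detections=EventSeries("r_detection", np.asarray([t_of(k) for k in dets])),
        rising=EventSeries("ttl_rising", np.asarray([t_of(k) for k in rising])),
        falling=EventSeries("ttl_falling", np.asarray([t_of(k) for k in falling])),
        hr_series=hr_series,
        threshold=thr_trace,
        grid=grid,
    )
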