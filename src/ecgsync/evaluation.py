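"""Error-rate and timing-precision evaluation of detector runs.

Rising edges are matched to reference R times by greedy nearest-neighbor
pairing inside a window; unmatched edges are false positives, unmatched
references false negatives (typed ``stuck_high`` when the TTL line is still
high at the reference time).  Timing precision compares actual edges to the
ideal edge train, which can only be built ex post: one edge per reference
derivative maximum, shifted back by the configured phase offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .detector_core import (
    DetectorConfig,
    EventSeries,
    InputError,
    StreamResult,
    UniformSignal,
    resample_to_grid,
    run_streaming,
)

__all__ = [
    "MatchResult",
    "EvaluationReport",
    "WARMUP_CYCLES",
    "ideal_ttl",
    "match_edges",
    "error_rates",
    "timing_stats",
    "derivative_peak_times",
    "default_window",
    "evaluate_trace",
    "plot_overlay",
]

#: Leading cardiac cycles excluded from scoring.  No valid period estimate
#: exists before two detections, so the first edge a compliant detector can
#: emit belongs to the third cycle.
WARMUP_CYCLES = 2

FN_MISSED = "missed"
FN_STUCK_HIGH = "stuck_high"


@dataclass(frozen=True)
class MatchResult:
    """Outcome of pairing rising edges with reference R times."""

    matched: Tuple[Tuple[float, float], ...]  # (reference time, edge time)
    false_positives: Tuple[float, ...]
    false_negatives: Tuple[Tuple[float, str], ...]  # (reference time, fn type)

    @property
    def n_fp(self) -> int:
        return len(self.false_positives)

    @property
    def n_fn(self) -> int:
        return len(self.false_negatives)


@dataclass(frozen=True)
class EvaluationReport:
    """One result row: error percentages plus timing-offset statistics."""

    trace_id: str
    n_cycles: int
    fp_pct: float
    fn_pct: float
    error_pct: float
    dt_mean_ms: float
    dt_std_ms: float
    reference: str = "derivative_max"  # or "r_truth"

    def to_record(self) -> Dict[str, object]:
        return {
            "trace_id": self.trace_id,
            "n_cycles": self.n_cycles,
            "fp_pct": round(self.fp_pct, 2),
            "fn_pct": round(self.fn_pct, 2),
            "error_pct": round(self.error_pct, 2),
            "dt_mean_ms": None if math.isnan(self.dt_mean_ms) else round(self.dt_mean_ms, 2),
            "dt_std_ms": None if math.isnan(self.dt_std_ms) else round(self.dt_std_ms, 2),
            "reference": self.reference,
        }

    def summary(self) -> str:
        return (
            f"trace {self.trace_id}: {self.n_cycles} cycles | "
            f"FP {self.fp_pct:.2f}% FN {self.fn_pct:.2f}% error {self.error_pct:.2f}% | "
            f"dt {self.dt_mean_ms:.2f} +/- {self.dt_std_ms:.2f} ms "
            f"(reference: {self.reference})"
        )


def ideal_ttl(references: EventSeries, cfg: DetectorConfig) -> EventSeries:
    """Ex-post ideal rising edges: ``r(k) - dt_mp`` for reference index >= 2.

    The first two references are skipped, mirroring the warm-up: until two
    detections exist there is no period estimate and no edge to aim at.
    """
    if len(references) < 2:
        raise InputError("at least two reference times are required")
    times = references.times[WARMUP_CYCLES:] - cfg.dt_mp
    return EventSeries("ttl_rising", times)


def match_edges(
    edges: EventSeries,
    r_truth: EventSeries,
    ttl: UniformSignal,
    window: float,
) -> MatchResult:
    """Greedy nearest-neighbor matching of rising edges to reference times.

    Each edge and each reference participates in at most one pair; pairs
    further apart than ``window`` seconds are never formed.  Unmatched
    references are typed ``stuck_high`` when the TTL trace is high at the
    reference time, else ``missed``.
    """
    if window <= 0:
        raise InputError("matching window must be > 0")
    et = np.asarray(edges.times)
    rt = np.asarray(r_truth.times)
    candidates: List[Tuple[float, int, int]] = []
    for i, e in enumerate(et):
        j0 = int(np.searchsorted(rt, e - window))
        j1 = int(np.searchsorted(rt, e + window, side="right"))
        for j in range(j0, j1):
            candidates.append((abs(e - rt[j]), i, j))
    candidates.sort()
    edge_used = np.zeros(et.size, dtype=bool)
    truth_used = np.zeros(rt.size, dtype=bool)
    matched: List[Tuple[float, float]] = []
    for _, i, j in candidates:
        if edge_used[i] or truth_used[j]:
            continue
        edge_used[i] = True
        truth_used[j] = True
        matched.append((float(rt[j]), float(et[i])))
    matched.sort()
    fps = tuple(float(e) for e, used in zip(et, edge_used) if not used)
    fns: List[Tuple[float, str]] = []
    for r, used in zip(rt, truth_used):
        if used:
            continue
        try:
            high = ttl.level_at(float(r)) == 1
        except Exception:
            high = False
        fns.append((float(r), FN_STUCK_HIGH if high else FN_MISSED))
    return MatchResult(tuple(matched), fps, tuple(fns))


def error_rates(m: MatchResult, n_r: int) -> Tuple[float, float, float]:
    """FP, FN and combined error as percentages of ``n_r`` R-waves."""
    if n_r <= 0:
        raise InputError("n_r must be > 0")
    fp_pct = 100.0 * m.n_fp / n_r
    fn_pct = 100.0 * m.n_fn / n_r
    return fp_pct, fn_pct, fp_pct + fn_pct


def timing_stats(
    actual: Sequence[float], ideal: Sequence[float]
) -> Tuple[float, float]:
    """Mean and sample STD (ms) of ``ideal - actual`` over matched pairs.

    Positive values mean the actual edge fired early (advanced).
    """
    actual = np.asarray(actual, dtype=float)
    ideal = np.asarray(ideal, dtype=float)
    if actual.size != ideal.size:
        raise InputError("actual and ideal edge lists must pair up")
    if actual.size < 2:
        raise InputError("at least two matched pairs are required")
    dt_ms = (ideal - actual) * 1000.0
    return float(np.mean(dt_ms)), float(np.std(dt_ms, ddof=1))


def derivative_peak_times(
    ecg: UniformSignal,
    cfg: DetectorConfig,
    r_truth: EventSeries,
    half_window: float = 0.06,
) -> np.ndarray:
    """Per-beat time of the maximum tick-grid difference, computed offline.

    This is the ex-post reference the trigger aims at: the trace is put on
    the detector's own tick grid and the two-point difference is maximised
    inside ``+/- half_window`` of each annotated R time.
    """
    grid = resample_to_grid(ecg, cfg)
    d = np.diff(grid.samples)
    out = np.empty(len(r_truth))
    for i, r in enumerate(r_truth.times):
        k0 = max(0, int(math.floor((r - half_window - grid.start_time) / cfg.tick)))
        k1 = min(d.size, int(math.ceil((r + half_window - grid.start_time) / cfg.tick)))
        if k0 >= k1:
            raise InputError(f"reference time {r} has no surrounding samples")
        k = k0 + int(np.argmax(d[k0:k1]))
        out[i] = grid.start_time + k * cfg.tick
    return out


def default_window(r_truth: EventSeries) -> float:
    """Matching window: min(150 ms, 0.4 * median RR interval)."""
    rr = np.diff(r_truth.times)
    if rr.size == 0:
        return 0.150
    return float(min(0.150, 0.4 * np.median(rr)))


def evaluate_trace(
    ecg: UniformSignal,
    r_truth: EventSeries,
    cfg: DetectorConfig,
    trace_id: str = "trace",
    window: Optional[float] = None,
    use_truth_reference: bool = False,
    result: Optional[StreamResult] = None,
) -> Tuple[EvaluationReport, MatchResult, StreamResult]:
    """Run the detector on one trace and score it end to end.

    The first two cycles (warm-up) are excluded from ``n_cycles``, from
    FN counting, and edges earlier than the first scored cycle's window are
    discarded as warm-up transients.  Timing statistics use the ex-post
    ideal edges (reference derivative maxima, or the annotations themselves
    when ``use_truth_reference`` is set).
    """
    if len(r_truth) < WARMUP_CYCLES + 1:
        raise InputError("need more than two annotated cycles to evaluate")
    if result is None:
        result = run_streaming(ecg, cfg)
    if window is None:
        window = default_window(r_truth)

    if use_truth_reference:
        refs = np.asarray(r_truth.times, dtype=float)
        reference = "r_truth"
    else:
        refs = derivative_peak_times(ecg, cfg, r_truth)
        reference = "derivative_max"

    scored_truth = EventSeries(r_truth.kind, r_truth.times[WARMUP_CYCLES:])
    scored_refs = refs[WARMUP_CYCLES:]
    ideal_times = scored_refs - cfg.dt_mp
    # score only edges aimed at the annotated cycles: warm-up transients
    # before the first scored cycle and the trailing edge predicting the
    # beat after the last annotation are both out of scope
    keep = (result.rising.times >= ideal_times[0] - window) & (
        result.rising.times <= ideal_times[-1] + window
    )
    edges = EventSeries("ttl_rising", result.rising.times[keep])

    m = match_edges(edges, scored_truth, result.ttl, window)
    n_cycles = len(scored_truth)
    fp_pct, fn_pct, err_pct = error_rates(m, n_cycles)

    ideal_of = {float(r): float(i) for r, i in zip(scored_truth.times, ideal_times)}
    actual = [e for r, e in m.matched]
    ideal = [ideal_of[r] for r, _ in m.matched]
    if len(actual) >= 2:
        dt_mean, dt_std = timing_stats(actual, ideal)
    else:
        dt_mean, dt_std = float("nan"), float("nan")

    report = EvaluationReport(
        trace_id=trace_id,
        n_cycles=n_cycles,
        fp_pct=fp_pct,
        fn_pct=fn_pct,
        error_pct=err_pct,
        dt_mean_ms=dt_mean,
        dt_std_ms=dt_std,
        reference=reference,
    )
    return report, m, result


def plot_overlay(
    ecg: UniformSignal,
    ttl: UniformSignal,
    ideal_edges: Optional[EventSeries],
    path: str,
    title: str = "ECG / TTL overlay",
) -> None:
    """Write a figure overlaying the ECG, the TTL output and ideal edges."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(11, 4))
    ax.plot(ecg.times(), ecg.samples, color="tab:blue", lw=0.9, label="ECG")
    scale = float(np.max(np.abs(ecg.samples))) or 1.0
    ax.plot(
        ttl.times(),
        ttl.samples * scale,
        color="tab:red",
        lw=1.2,
        label="TTL",
        drawstyle="steps-post",
    )
    if ideal_edges is not None and len(ideal_edges):
        for i, e in enumerate(ideal_edges.times):
            ax.axvline(
                e,
                color="black",
                ls="--",
                lw=0.8,
                label="ideal edge" if i == 0 else None,
            )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (arb. units)")
    ax.set_title(title)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
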