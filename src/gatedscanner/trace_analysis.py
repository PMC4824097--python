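"""Analysis of single-molecule translocation traces.

Pipeline: block-average the raw 60 Hz trace to the 3 Hz analysis bandwidth,
compute local velocities by sliding least-squares, detect pauses as runs of
sub-threshold velocity subject to the 0.33 s instrument resolution, summarize
pause statistics per ensemble, and compare dwell samples between variants with
a Mood's median test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import median_test as _scipy_median_test

from .simulate import Trace


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for trace filtering, velocity profiling and pause detection.

    ``min_pause_s`` is the temporal resolution of the instrument: dwells
    shorter than this cannot be detected and reported events are censored at
    this limit.  A sample counts as paused when its local velocity falls below
    ``pause_velocity_frac`` times the trace's own pre-Chi mean velocity.
    ``chi_window_bp`` classifies events as at-Chi; it spans the Chi locus plus
    a 50 bp margin on each side for positional noise.  ``pre_chi_guard_bp`` is
    the margin before the window excluded from the pre-Chi velocity estimate
    so that windows straddling the first Chi do not bias it.
    """

    filter_rate_hz: float = 3.0
    min_pause_s: float = 0.33
    velocity_window_s: float = 0.67
    pause_velocity_frac: float = 0.25
    chi_window_bp: tuple = (4538.0, 4988.0)
    profile_bin_bp: float = 100.0
    pre_chi_guard_bp: float = 250.0

    def __post_init__(self) -> None:
        if self.min_pause_s <= 0:
            raise ValueError("min_pause_s must be > 0")
        if not 0 < self.pause_velocity_frac < 1:
            raise ValueError("pause_velocity_frac must be in (0, 1)")
        if self.chi_window_bp[1] <= self.chi_window_bp[0]:
            raise ValueError("chi_window_bp must be an increasing (start, end) pair")


@dataclass(frozen=True)
class PauseEvent:
    """One detected dwell: onset, duration, mean position, at-Chi flag."""

    start_s: float
    duration_s: float
    position_bp: float
    at_chi: bool


@dataclass
class PauseStats:
    """Censored summary of detected at-Chi pauses over an ensemble of traces."""

    n_events: int
    n_traces: int
    frequency: float
    median_s: float
    mean_s: float
    q25_s: float
    q75_s: float
    min_s: float
    max_s: float


@dataclass
class MedianTestResult:
    """Mood's median test: 2x2 above/not-above table, chi-square, p-value."""

    table: np.ndarray
    statistic: float
    p_value: float
    grand_median: float


def filter_trace(trace: Trace, cfg: AnalysisConfig) -> Trace:
    """Reduce a trace to the analysis bandwidth by non-overlapping block averages.

    Block size is round(sample_rate / filter_rate) raw samples (20 for
    60 -> 3 Hz); the output sample rate is ``filter_rate_hz``.
    """
    block = int(round(trace.sample_rate_hz / cfg.filter_rate_hz))
    if block < 1:
        raise ValueError("filter rate exceeds the sampling rate")
    n_blocks = len(trace) // block
    if n_blocks < 1:
        raise ValueError("trace shorter than one filter block")
    pos = trace.position_bp[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    t = trace.time_s[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return Trace(
        time_s=t,
        position_bp=pos,
        events=trace.events,
        variant=trace.variant,
        seed=trace.seed,
    )


def local_velocity(trace: Trace, cfg: AnalysisConfig) -> np.ndarray:
    """Local velocity (bp/s) at every sample: sliding least-squares slope.

    The window spans ``velocity_window_s`` (at least two samples) and is
    truncated at the trace edges.
    """
    dt = 1.0 / trace.sample_rate_hz
    w = max(2, int(round(cfg.velocity_window_s / dt)))
    n = len(trace)
    if n < 2:
        raise ValueError("trace too short for a velocity estimate")
    half_lo = (w - 1) // 2
    t = trace.time_s
    x = trace.position_bp
    vel = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, lo + w)
        lo = max(0, hi - w)
        tt = t[lo:hi]
        xx = x[lo:hi]
        tc = tt - tt.mean()
        vel[i] = float(np.dot(tc, xx - xx.mean()) / np.dot(tc, tc))
    return vel


def pre_chi_mean_velocity(
    trace: Trace, cfg: AnalysisConfig, velocity: np.ndarray | None = None
) -> float:
    """Mean local velocity over the region before the Chi window (minus the
    guard margin), the trace's own reference translocation rate."""
    if velocity is None:
        velocity = local_velocity(trace, cfg)
    cutoff = cfg.chi_window_bp[0] - cfg.pre_chi_guard_bp
    mask = trace.position_bp < cutoff
    if not mask.any():
        raise ValueError("trace has no samples before the Chi window")
    return float(velocity[mask].mean())


def detect_pauses(
    trace: Trace, cfg: AnalysisConfig, velocity: np.ndarray | None = None
) -> list[PauseEvent]:
    """Detect pauses on a filtered trace by velocity-threshold run lengths.

    Maximal runs of samples with velocity below ``pause_velocity_frac`` times
    the pre-Chi mean velocity become events.  The dwell estimate integrates
    the stationary coverage 1 - v/v_ref over the run and the two adjacent
    samples, which resolves durations below the filtered sample spacing
    instead of quantizing them to whole samples; events shorter than
    ``min_pause_s`` are censored away.  Events are labelled at-Chi when their
    mean position falls inside ``chi_window_bp``.
    """
    if velocity is None:
        velocity = local_velocity(trace, cfg)
    v_ref = pre_chi_mean_velocity(trace, cfg, velocity)
    threshold = cfg.pause_velocity_frac * v_ref
    dt = 1.0 / trace.sample_rate_hz
    paused = velocity < threshold
    coverage = np.clip(1.0 - velocity / v_ref, 0.0, None)

    events: list[PauseEvent] = []
    n = len(paused)
    i = 0
    while i < n:
        if not paused[i]:
            i += 1
            continue
        j = i
        while j < n and paused[j]:
            j += 1
        lo = i - 1 if i > 0 and not paused[i - 1] else i
        hi = j + 1 if j < n and not paused[j] else j
        duration = float(coverage[lo:hi].sum()) * dt
        if duration >= cfg.min_pause_s:
            mean_pos = float(trace.position_bp[i:j].mean())
            at_chi = cfg.chi_window_bp[0] <= mean_pos <= cfg.chi_window_bp[1]
            events.append(
                PauseEvent(
                    start_s=float(trace.time_s[i]),
                    duration_s=duration,
                    position_bp=mean_pos,
                    at_chi=at_chi,
                )
            )
        i = j
    return events


def pause_statistics(
    events_per_trace: list[list[PauseEvent]], cfg: AnalysisConfig
) -> PauseStats:
    """Censored ensemble summary of at-Chi pauses.

    Frequency is the fraction of traces with at least one at-Chi event;
    duration summaries are computed over detected at-Chi events only (all of
    which exceed ``min_pause_s`` by construction).
    """
    n_traces = len(events_per_trace)
    if n_traces == 0:
        raise ValueError("no traces given")
    at_chi = [
        [e for e in evts if e.at_chi] for evts in events_per_trace
    ]
    durations = np.asarray([e.duration_s for evts in at_chi for e in evts])
    frequency = sum(1 for evts in at_chi if evts) / n_traces
    if len(durations) == 0:
        nan = float("nan")
        return PauseStats(0, n_traces, frequency, nan, nan, nan, nan, nan, nan)
    return PauseStats(
        n_events=len(durations),
        n_traces=n_traces,
        frequency=frequency,
        median_s=float(np.median(durations)),
        mean_s=float(durations.mean()),
        q25_s=float(np.percentile(durations, 25)),
        q75_s=float(np.percentile(durations, 75)),
        min_s=float(durations.min()),
        max_s=float(durations.max()),
    )


def moods_median_test(a, b, correction: bool = True) -> MedianTestResult:
    """Mood's median test for equality of medians of two dwell samples.

    Pools both samples, counts values above vs not-above the grand median
    (ties count as not-above) in a 2x2 table, and applies a chi-square test
    with 1 df (Yates continuity correction by default).  Symmetric in (a, b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate samples: all pooled values are identical")
    stat, p, med, table = _scipy_median_test(
        a, b, ties="below", correction=correction
    )
    return MedianTestResult(
        table=np.asarray(table), statistic=float(stat), p_value=float(p),
        grand_median=float(med),
    )


def mean_velocity_profile(
    traces: list[Trace], cfg: AnalysisConfig, length_bp: float | None = None
) -> "pd.DataFrame":
    """Mean local velocity as a function of position, pooled over traces.

    Velocities of all traces are binned by the (noisy) sample position in
    bins of ``profile_bin_bp``; bins with no samples are omitted.  Returns a
    DataFrame with bin_start_bp, bin_end_bp, mean_velocity, n.
    """
    import pandas as pd

    if not traces:
        raise ValueError("no traces given")
    if length_bp is None:
        length_bp = max(float(tr.position_bp.max()) for tr in traces)
    edges = np.arange(0.0, length_bp + cfg.profile_bin_bp, cfg.profile_bin_bp)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for tr in traces:
        vel = local_velocity(tr, cfg)
        idx = np.digitize(tr.position_bp, edges) - 1
        ok = (idx >= 0) & (idx < len(sums))
        np.add.at(sums, idx[ok], vel[ok])
        np.add.at(counts, idx[ok], 1)
    nonempty = counts > 0
    return pd.DataFrame(
        {
            "bin_start_bp": edges[:-1][nonempty],
            "bin_end_bp": edges[1:][nonempty],
            "mean_velocity": sums[nonempty] / counts[nonempty],
            "n": counts[nonempty],
        }
    )


def analyze_traces(
    traces: list[Trace], cfg: AnalysisConfig
) -> tuple[list[list[PauseEvent]], PauseStats]:
    """Full per-ensemble analysis: filter, detect, summarize."""
    events_per_trace = []
    for tr in traces:
        filtered = filter_trace(tr, cfg)
        events_per_trace.append(detect_pauses(filtered, cfg))
    return events_per_trace, pause_statistics(events_per_trace, cfg)
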