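"""Retinogeniculate recording analytics.

Covers the slice-physiology readouts of circuit refinement:

- `count_inputs`: automated counting of RGC inputs from an EPSC
  response staircase.  Gradually increasing optic-tract stimulation
  recruits axons serially; each recruited axon adds a step to the peak
  EPSC amplitude.  Steps are found by penalized least-squares
  change-point segmentation (exact dynamic program) followed by a
  minimum-step gate, automating what is classically counted by eye.
- `detect_mepsc`: threshold-crossing miniature-EPSC detection (default
  -9 pA) on a rolling-median-baselined trace.
- `paired_pulse_ratio`: second/first EPSC amplitude with the decay tail
  of the first response removed by exponential extrapolation.
- `fiber_metrics` / `ampa_nmda_ratio`: single-fiber fraction of the
  maximal response, and the AMPAR/NMDAR peak ratio.

Polarity convention: recorded inward currents are negative in traces;
response-curve amplitudes are folded to positive magnitudes (nA) at the
:class:`~synquant.synthio.ResponseCurve` boundary, and all ratios are
computed on magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .synthio import ResponseCurve, Trace

__all__ = [
    "InputCountResult",
    "MepscEvent",
    "EventTrain",
    "count_inputs",
    "detect_mepsc",
    "paired_pulse_ratio",
    "fiber_metrics",
    "ampa_nmda_ratio",
    "late_peak",
]


@dataclass
class InputCountResult:
    """Result of EPSC-staircase input counting."""

    n_inputs: int
    step_levels_nA: list[float]  # plateau values, first entry is the zero level
    single_fiber_nA: float
    max_nA: float
    discard: bool = False  # amplitude dropped along the staircase


def _segment_means(amps: np.ndarray, penalty: float) -> list[tuple[float, int]]:
    """Optimal piecewise-constant fit: minimize sum of within-segment SSE
    plus ``penalty`` per segment, by exact dynamic programming.  Returns
    (mean, size) per segment in order."""
    n = len(amps)
    s1 = np.concatenate([[0.0], np.cumsum(amps)])
    s2 = np.concatenate([[0.0], np.cumsum(amps**2)])

    def sse(i: int, j: int) -> float:  # segment [i, j)
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = 0.0
    for j in range(1, n + 1):
        for i in range(j):
            c = best[i] + sse(i, j) + penalty
            # Ties resolved toward the later split (fewer, longer segments
            # win because earlier i is tried first only on strict '<').
            if c < best[j] - 1e-12:
                best[j] = c
                prev[j] = i
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(prev[bounds[-1]]))
    bounds = bounds[::-1]
    out = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        out.append(((s1[j] - s1[i]) / (j - i), j - i))
    return out


def _merge_levels(
    levels: list[tuple[float, int]], min_step: float
) -> list[tuple[float, int]]:
    """Agglomeratively merge adjacent plateaus whose level difference is
    below ``min_step`` (weighted means; smallest difference first)."""
    levels = list(levels)
    while len(levels) > 1:
        diffs = [abs(levels[k + 1][0] - levels[k][0]) for k in range(len(levels) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= min_step:
            break
        (m1, n1), (m2, n2) = levels[k], levels[k + 1]
        levels[k : k + 2] = [((m1 * n1 + m2 * n2) / (n1 + n2), n1 + n2)]
    return levels


def count_inputs(
    curve: ResponseCurve,
    noise_sd_nA: float = 0.02,
    min_step_nA: float = 0.1,
) -> InputCountResult:
    """Count synaptic inputs from an EPSC staircase.

    Amplitudes are segmented into plateaus by penalized least-squares
    change-point detection (penalty ``2 * noise_sd^2 * ln(n)`` per
    segment, a BIC-type choice); adjacent plateaus closer than
    ``min_step_nA`` are merged.  ``n_inputs`` is the number of upward
    transitions from the zero plateau onward; a downward transition marks
    the recording for discard (a dropping EPSC invalidates the cell).
    """
    amps = curve.amplitudes_nA
    if len(amps) < 5:
        raise ValueError("need at least 5 staircase points")
    if min_step_nA < 3 * noise_sd_nA:
        raise ValueError("min_step_nA must be at least 3x noise_sd_nA")

    penalty = 2.0 * noise_sd_nA**2 * np.log(len(amps))
    levels = _merge_levels(_segment_means(amps, penalty), min_step_nA)

    values = [lv for lv, _ in levels]
    # Anchor the zero plateau: if the first plateau is itself a real step,
    # a virtual zero level precedes it.
    if abs(values[0]) >= min_step_nA:
        values = [0.0] + values
    diffs = np.diff(values)
    discard = bool(np.any(diffs < 0))
    n_inputs = int(np.sum(diffs > 0))
    zero = values[0]
    single_fiber = float(values[1] - zero) if len(values) > 1 else 0.0
    max_amp = float(values[-1] - zero) if len(values) > 1 else 0.0
    return InputCountResult(n_inputs, [float(v) for v in values], single_fiber,
                            max_amp, discard)


@dataclass
class MepscEvent:
    time_s: float
    amplitude_pA: float  # negative (inward), baseline-to-peak
    rise_ms: float = float("nan")
    decay_ms: float = float("nan")


@dataclass
class EventTrain:
    events: list[MepscEvent]
    duration_s: float
    threshold_pA: float

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([e.time_s for e in self.events])

    @property
    def amplitudes_pA(self) -> np.ndarray:
        return np.array([e.amplitude_pA for e in self.events])

    @property
    def intervals_s(self) -> np.ndarray:
        return np.diff(self.times_s)

    @property
    def rate_hz(self) -> float:
        return len(self.events) / self.duration_s

    @property
    def median_amplitude_pA(self) -> float:
        return float(np.median(self.amplitudes_pA)) if self.events else float("nan")


def _rolling_median_baseline(
    samples: np.ndarray, fs: float, window_ms: float, decimate_ms: float = 5.0
) -> np.ndarray:
    """Slowly varying baseline: median filter on a decimated copy of the
    trace, linearly interpolated back to full rate.  Decimation makes the
    180 s x 20 kHz traces tractable without changing the estimate, since
    the baseline varies on a much slower timescale than the decimation."""
    step = max(1, int(round(decimate_ms * fs / 1000.0)))
    dec = samples[::step]
    w = max(3, int(round(window_ms / decimate_ms)) | 1)
    med = ndimage.median_filter(dec, size=w, mode="nearest")
    t_dec = np.arange(len(dec)) * step
    return np.interp(np.arange(len(samples)), t_dec, med)


def detect_mepsc(
    trace: Trace,
    threshold_pA: float = -9.0,
    min_separation_ms: float = 10.0,
    baseline_window_ms: float = 200.0,
    smoothing_ms: float = 0.2,
) -> EventTrain:
    """Detect miniature EPSCs by negative threshold crossing.

    A rolling-median baseline (``baseline_window_ms``) is subtracted, the
    residual is lightly Gaussian-smoothed (``smoothing_ms``), and every
    contiguous run of samples at or below ``threshold_pA`` becomes a
    candidate event with amplitude measured baseline-to-peak at the run
    minimum.  Events closer than ``min_separation_ms`` are merged to the
    larger peak.  Amplitudes are negative; a saturated (clipped) trace
    triggers a warning with the clipped-sample count.
    """
    if trace.duration_s < 1.0:
        raise ValueError("trace must be at least 1 s long")
    fs = trace.sampling_hz
    samples = np.asarray(trace.samples_pA, dtype=float)
    for extreme in (samples.min(), samples.max()):
        if extreme == 0.0:
            continue  # an exactly-zero baseline is not ADC saturation
        n_clip = _clipped_run(samples, extreme)
        if n_clip:
            warnings.warn(
                f"trace appears clipped at {extreme:.6g} pA "
                f"({n_clip} saturated samples)",
                stacklevel=2,
            )
    baseline = _rolling_median_baseline(samples, fs, baseline_window_ms)
    resid = samples - baseline
    if smoothing_ms > 0:
        resid = ndimage.gaussian_filter1d(resid, sigma=smoothing_ms * fs / 1000.0)

    below = resid <= threshold_pA
    if not below.any():
        return EventTrain([], trace.duration_s, threshold_pA)
    idx = np.flatnonzero(below)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], run_breaks + 1])
    run_ends = np.concatenate([run_breaks, [len(idx) - 1]])

    events: list[MepscEvent] = []
    for s, e in zip(run_starts, run_ends):
        lo, hi = idx[s], idx[e] + 1
        peak = lo + int(np.argmin(resid[lo:hi]))
        events.append(MepscEvent(peak / fs, float(resid[peak])))

    min_sep = min_separation_ms / 1000.0
    merged: list[MepscEvent] = []
    for ev in events:
        if merged and ev.time_s - merged[-1].time_s < min_sep:
            if ev.amplitude_pA < merged[-1].amplitude_pA:
                merged[-1] = ev
        else:
            merged.append(ev)

    for ev in merged:
        _fill_kinetics(ev, resid, fs)
    return EventTrain(merged, trace.duration_s, threshold_pA)


def _clipped_run(samples: np.ndarray, extreme: float) -> int:
    """Number of saturated samples if the extreme value forms runs of
    repeated identical samples (a hallmark of ADC clipping)."""
    at = samples == extreme
    n = int(at.sum())
    if n < 5:
        return 0
    # Require at least one run of >= 5 consecutive identical samples.
    runs = np.diff(np.flatnonzero(at))
    return n if np.any(runs == 1) and n >= 5 else 0


def _fill_kinetics(ev: MepscEvent, resid: np.ndarray, fs: float) -> None:
    """10-90%-style rise and half-decay times from the smoothed residual."""
    peak = int(round(ev.time_s * fs))
    half = ev.amplitude_pA / 2.0
    w = int(0.02 * fs)
    pre = resid[max(0, peak - w) : peak + 1]
    post = resid[peak : peak + w]
    above_pre = np.flatnonzero(pre > half)
    above_post = np.flatnonzero(post > half)
    if above_pre.size:
        ev.rise_ms = (len(pre) - 1 - above_pre[-1]) / fs * 1000.0
    if above_post.size:
        ev.decay_ms = above_post[0] / fs * 1000.0


def _fit_decay_tail(
    t: np.ndarray, d: np.ndarray, a0: float
) -> "callable":
    """Fit a (bi)exponential decay d(t) ~ a1 e^-t/tau1 + a2 e^-t/tau2 to the
    positive deflection after the first EPSC peak; returns an extrapolator.
    Falls back to a single exponential, then to zero, if the fit fails."""
    span = max(t[-1], 1e-3)

    def biexp(tt, a1, tau1, a2, tau2):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    def monoexp(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        p, _ = optimize.curve_fit(
            biexp, t, d,
            p0=[0.7 * a0, span / 3.0, 0.3 * a0, span],
            bounds=([0, 1e-4, 0, 1e-4], [5 * a0, 10 * span, 5 * a0, 50 * span]),
            maxfev=2000,
        )
        return lambda tt: biexp(tt, *p)
    except Exception:
        pass
    try:
        p, _ = optimize.curve_fit(
            monoexp, t, d, p0=[a0, span / 2.0],
            bounds=([0, 1e-4], [5 * a0, 50 * span]), maxfev=1000,
        )
        return lambda tt: monoexp(tt, *p)
    except Exception:
        return lambda tt: np.zeros_like(np.asarray(tt, dtype=float))


def paired_pulse_ratio(
    trace: Trace,
    stim_times_s: tuple[float, float],
    smoothing_ms: float = 0.2,
    noise_floor_sd: float = 5.0,
) -> float:
    """Paired-pulse ratio: second EPSC amplitude over first EPSC amplitude.

    The first amplitude is baseline-to-peak after the first stimulus.  The
    decaying tail of the first response is fit with a biexponential on the
    inter-pulse segment and extrapolated under the second response; the
    second amplitude is the post-stimulus peak minus that tail.  Either
    amplitude below ``noise_floor_sd`` pre-stimulus noise SDs raises (a
    ratio against noise is undefined — a trace whose second pulse is
    missing errors rather than returning 0).
    """
    t1, t2 = stim_times_s
    if t2 <= t1:
        raise ValueError("stim times must be ordered t1 < t2")
    fs = trace.sampling_hz
    samples = np.asarray(trace.samples_pA, dtype=float)
    i1, i2 = int(round(t1 * fs)), int(round(t2 * fs))
    if i1 <= 0 or i2 >= len(samples):
        raise ValueError("stimulus times outside the trace")

    if smoothing_ms > 0:
        smoothed = ndimage.gaussian_filter1d(samples, sigma=smoothing_ms * fs / 1000.0)
    else:
        smoothed = samples
    pre = samples[: max(2, int(0.9 * i1))]
    baseline = float(np.median(pre))
    noise_sd = float(np.std(pre))

    # Positive deflection (inward currents fold positive).
    d = baseline - smoothed
    p1 = i1 + int(np.argmax(d[i1:i2]))
    a1 = float(d[p1])
    if a1 < noise_floor_sd * max(noise_sd, 1e-12):
        raise ValueError("first EPSC amplitude below the noise floor")

    # Tail of the first response, fit between the first peak and t2.
    fit_lo = min(p1 + max(3, int(0.002 * fs)), i2 - 2)
    seg_t = (np.arange(fit_lo, i2 - 1) - p1) / fs
    seg_d = d[fit_lo : i2 - 1]
    tail_end = float(np.median(seg_d[-max(2, int(0.002 * fs)) :])) if len(seg_d) else 0.0
    if len(seg_d) >= 8 and tail_end > 2.0 * noise_sd:
        tail = _fit_decay_tail(seg_t, seg_d, a1)
    elif tail_end > 2.0 * noise_sd:
        tail = lambda tt: np.full_like(np.asarray(tt, float), tail_end)
    else:
        tail = lambda tt: np.zeros_like(np.asarray(tt, dtype=float))

    win2 = slice(i2, min(len(samples), i2 + int(0.1 * fs)))
    p2 = i2 + int(np.argmax(d[win2]))
    a2 = float(d[p2]) - float(tail((p2 - p1) / fs))
    if a2 < noise_floor_sd * max(noise_sd, 1e-12):
        raise ValueError("second EPSC amplitude below the noise floor")
    return a2 / a1


def fiber_metrics(result: InputCountResult) -> tuple[float, float]:
    """(fiber_fraction, max_amplitude_nA) from an input-count result.

    The fiber fraction is the putative single-fiber amplitude (first step)
    over the maximal (plateau) amplitude, in (0, 1]."""
    if result.n_inputs < 1:
        raise ValueError("need at least one input")
    if result.max_nA <= 0:
        raise ValueError("zero maximal amplitude")
    return result.single_fiber_nA / result.max_nA, result.max_nA


def late_peak(trace: Trace, stim_time_s: float,
              window_s: tuple[float, float] = (0.01, 0.05)) -> float:
    """Peak magnitude (pA) in a late window after the stimulus — the
    standard way to read the NMDAR component of a +40 mV response, after
    the fast AMPAR component has decayed.  Window bounds are relative to
    the stimulus time."""
    fs = trace.sampling_hz
    i0 = int(round((stim_time_s + window_s[0]) * fs))
    i1 = int(round((stim_time_s + window_s[1]) * fs))
    samples = np.asarray(trace.samples_pA, dtype=float)
    if not 0 <= i0 < i1 <= len(samples):
        raise ValueError("late window outside the trace")
    baseline = float(np.median(samples[: max(2, int(0.9 * stim_time_s * fs))]))
    return float(np.max(np.abs(samples[i0:i1] - baseline)))


def ampa_nmda_ratio(peak_at_minus70_nA: float, peak_at_plus40_nA: float) -> float:
    """AMPAR-EPSC / NMDAR-EPSC peak ratio (both magnitudes, nA)."""
    if peak_at_minus70_nA <= 0 or peak_at_plus40_nA < 0:
        raise ValueError("peak magnitudes must be positive after polarity folding")
    if peak_at_plus40_nA == 0:
        raise ValueError("zero NMDAR peak")
    return peak_at_minus70_nA / peak_at_plus40_nA
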