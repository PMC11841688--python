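"""Head- and eye-trace preprocessing.

Head traces are zero-phase lowpass filtered, segmented into sweeps at
direction reversals, and summarized by the median velocity over a fractional
region of interest of the judged sweep. Eye traces are confidence-gated,
gap-filled, smoothed with a frequency-domain Gaussian, differentiated, and
cleaned of saccades by jerk thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import signal

from .exceptions import ValidationError

__all__ = [
    "Channel",
    "Trace",
    "SweepSegmentation",
    "VelocityDistribution",
    "EyePreprocessResult",
    "EyeSweepSummary",
    "lowpass_head",
    "smoothed_derivative",
    "detect_turn",
    "segment_sweeps",
    "sweep_bounds",
    "median_sweep_velocity",
    "fit_velocity_distribution",
    "expected_vor",
    "preprocess_eye",
    "remove_saccades",
    "sweep_eye_summary",
]

JERK_THRESHOLD_DEFAULT = 20_000.0  # deg/s^3
SACCADE_PAD_SAMPLES = 4
EYE_CONF_THRESHOLD = 0.6
EYE_SMOOTH_SIGMA_HZ = 16.0
EYE_EDGE_TRIM = 20


class Channel(str, Enum):
    HEAD_YAW = "head_yaw"
    EYE_AZIMUTH = "eye_azimuth"


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled angular position trace (deg) at ``rate`` Hz."""

    time: np.ndarray
    value: np.ndarray
    rate: float
    channel: Channel = Channel.HEAD_YAW
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("time and value must be 1-D and equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValidationError("time must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.rate, rtol=1e-3, atol=1e-6):
                raise ValidationError("sampling must be uniform at the declared rate")
        if self.confidence is not None:
            c = np.asarray(self.confidence, dtype=float)
            object.__setattr__(self, "confidence", c)
            if c.shape != v.shape:
                raise ValidationError("confidence length mismatch")

    @classmethod
    def from_values(
        cls,
        value: Sequence[float],
        rate: float,
        channel: Channel = Channel.HEAD_YAW,
        confidence: Sequence[float] | None = None,
    ) -> "Trace":
        value = np.asarray(value, dtype=float)
        time = np.arange(value.size) / rate
        conf = None if confidence is None else np.asarray(confidence, dtype=float)
        return cls(time, value, rate, channel, conf)


@dataclass(frozen=True)
class SweepSegmentation:
    """Direction-reversal boundaries (sample indices) and the judged sweep.

    Sweep ``k`` (1-based) runs from boundary ``k-1`` to boundary ``k`` of
    the augmented sequence [0, *reversals, n-1].
    """

    boundaries: np.ndarray
    judged_sweep: int = 3
    n_samples: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=int)
        object.__setattr__(self, "boundaries", b)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValidationError("boundaries must be strictly increasing")
        if self.judged_sweep < 1 or self.judged_sweep > b.size + 1:
            raise ValidationError("judged_sweep addresses a nonexistent sweep")


@dataclass(frozen=True)
class VelocityDistribution:
    """Gaussian summary of per-trial median head velocities."""

    mean: float
    variance: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValidationError("variance must be >= 0")
        if self.n_trials < 2:
            raise ValidationError("need n_trials >= 2")


def lowpass_head(trace: Trace, passband: float = 8.0) -> Trace:
    """Zero-phase Butterworth lowpass with its -3 dB point at ``passband``.

    Order-6 design, forward-backward filtered; the single-pass cutoff is
    pre-warped so the two-pass magnitude is -3 dB at the passband, and the
    two-pass attenuation one octave above exceeds 60 dB.
    """
    if passband >= trace.rate / 2:
        raise ValidationError("passband must be below Nyquist")
    order = 6
    # (fp/fc)^(2*order) = sqrt(2) - 1 puts the two-pass half-power point at fp
    fc = passband * (math.sqrt(2.0) - 1.0) ** (-1.0 / (2 * order))
    sos = signal.butter(order, fc, btype="low", fs=trace.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.value)
    return Trace(trace.time, filtered, trace.rate, trace.channel, trace.confidence)


def smoothed_derivative(value: np.ndarray, filter_len: int = 13) -> np.ndarray:
    """Causal finite-difference derivative estimate (arbitrary scale).

    Output sample ``k`` contrasts the most recent ``(filter_len-1)/2``
    samples against the same number ending ``filter_len-1`` samples back, so
    the estimate is centered ``(filter_len-1)/2`` samples in the past. The
    first ``filter_len - 1`` samples are NaN.
    """
    if filter_len < 3 or filter_len % 2 == 0:
        raise ValidationError("filter_len must be odd and >= 3")
    x = np.asarray(value, dtype=float)
    if x.size < filter_len:
        raise ValidationError("trace shorter than filter")
    half = (filter_len - 1) // 2
    kernel = np.concatenate([np.ones(half), [0.0], -np.ones(half)])
    kernel /= half * (half + 1)
    y = np.full(x.size, np.nan)
    valid = np.convolve(x, kernel, mode="valid")  # y[k] uses x[k-12..k]
    y[filter_len - 1 :] = valid
    return y


def detect_turn(trace: Trace, filter_len: int = 13) -> np.ndarray:
    """Sample indices at which the causally smoothed derivative flips sign.

    On a noise-free triangle wave the detection lags the true reversal by
    ``(filter_len + 1) / 2`` samples (zeros of the smoothed derivative do
    not count as a flip; the first strictly opposite sample does).
    """
    d = smoothed_derivative(trace.value, filter_len)
    finite = d[np.isfinite(d)]
    tol = 1e-9 * (np.abs(finite).max() if finite.size else 0.0)
    turns: list[int] = []
    prev_sign = 0
    for k in range(filter_len - 1, d.size):
        s = 0 if abs(d[k]) <= tol else int(np.sign(d[k]))
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            turns.append(k)
        prev_sign = s
    return np.asarray(turns, dtype=int)


def segment_sweeps(trace: Trace, judged_sweep: int = 3) -> SweepSegmentation:
    """Noise-free sweep segmentation from sign changes of the derivative.

    A boundary is placed where the (central-difference) derivative changes
    sign; an exact zero at the peak ties toward the earlier sample.
    """
    d = np.gradient(trace.value, trace.time)
    boundaries: list[int] = []
    prev_sign = 0
    for k in range(d.size):
        s = int(np.sign(d[k]))
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            b = k - 1 if k > 0 and np.sign(d[k - 1]) == 0 else k
            boundaries.append(b)
        prev_sign = s
    return SweepSegmentation(np.asarray(boundaries, dtype=int), judged_sweep,
                             n_samples=trace.value.size)


def sweep_bounds(seg: SweepSegmentation, n_samples: int | None = None) -> tuple[int, int]:
    """(start, end) sample indices of the judged sweep, end exclusive."""
    n = n_samples if n_samples is not None else seg.n_samples
    if n <= 0:
        raise ValidationError("segmentation carries no sample count")
    edges = np.concatenate([[0], seg.boundaries, [n - 1]])
    k = seg.judged_sweep
    if k >= edges.size:
        raise ValidationError("judged sweep out of range")
    return int(edges[k - 1]), int(edges[k]) + 1


def median_sweep_velocity(
    trace: Trace,
    seg: SweepSegmentation,
    roi: tuple[float, float] = (0.2, 0.6),
) -> float:
    """Median temporal-derivative velocity over a fractional ROI of the
    judged sweep (default 20%-60% of sweep length)."""
    lo, hi = roi
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError("roi must be a nonempty subinterval of [0, 1]")
    vel = np.gradient(trace.value, trace.time)
    start, end = sweep_bounds(seg, trace.value.size)
    length = end - start
    i0 = start + int(math.floor(lo * length))
    i1 = start + int(math.ceil(hi * length))
    if i1 - i0 < 3:
        raise ValidationError("ROI shorter than 3 samples")
    return float(np.median(vel[i0:i1]))


def fit_velocity_distribution(medians: Sequence[float]) -> VelocityDistribution:
    """Maximum-likelihood Gaussian summary: sample mean and population
    (ddof=0) variance."""
    vals = np.asarray(list(medians), dtype=float)
    if vals.size < 2:
        raise ValidationError("need at least 2 median velocities")
    return VelocityDistribution(float(vals.mean()), float(vals.var(ddof=0)),
                                int(vals.size))


def expected_vor(head_velocity: float, eye_offset_r: float = 0.1,
                 target_distance_d: float = 1.2) -> float:
    """Eye velocity of a perfectly compensatory VOR: -H * (1 + R/D)."""
    if target_distance_d <= 0:
        raise ValidationError("target distance must be > 0")
    return -head_velocity * (1.0 + eye_offset_r / target_distance_d)


@dataclass(frozen=True)
class EyePreprocessResult:
    """Cleaned eye waveform with derivatives, or a typed rejection."""

    rejected: bool
    reason: str = ""
    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    position: np.ndarray = field(default_factory=lambda: np.empty(0))
    velocity: np.ndarray = field(default_factory=lambda: np.empty(0))
    acceleration: np.ndarray = field(default_factory=lambda: np.empty(0))
    jerk: np.ndarray = field(default_factory=lambda: np.empty(0))
    frac_retained: float = 1.0


def preprocess_eye(
    trace: Trace,
    conf_threshold: float = EYE_CONF_THRESHOLD,
    smooth_sigma_hz: float = EYE_SMOOTH_SIGMA_HZ,
    edge_trim: int = EYE_EDGE_TRIM,
) -> EyePreprocessResult:
    """Confidence-gate, gap-fill, smooth, and differentiate an eye trace.

    Samples below ``conf_threshold`` are replaced by linear interpolation
    from the surviving samples; the whole waveform is rejected (a typed
    outcome, not an exception) if 50% or fewer samples survive. Smoothing
    multiplies the spectrum by a Gaussian with ``smooth_sigma_hz`` standard
    deviation; derivatives are central differences; ``edge_trim`` samples
    are dropped from each end.
    """
    if trace.confidence is None:
        raise ValidationError("eye preprocessing needs a confidence channel")
    conf = trace.confidence
    good = conf >= conf_threshold
    frac = float(good.mean())
    if frac <= 0.5:
        return EyePreprocessResult(True, f"only {frac:.0%} samples retained",
                                   frac_retained=frac)
    t, x = trace.time, trace.value
    pos = np.interp(t, t[good], x[good])
    # frequency-domain Gaussian smoothing: X(f) *= exp(-f^2 / (2 sigma^2))
    spectrum = np.fft.rfft(pos)
    freqs = np.fft.rfftfreq(pos.size, d=1.0 / trace.rate)
    spectrum *= np.exp(-(freqs**2) / (2.0 * smooth_sigma_hz**2))
    pos = np.fft.irfft(spectrum, n=pos.size)
    vel = np.gradient(pos, t)
    acc = np.gradient(vel, t)
    jerk = np.gradient(acc, t)
    sl = slice(edge_trim, pos.size - edge_trim if edge_trim else None)
    if pos[sl].size < 3:
        return EyePreprocessResult(True, "waveform too short after trimming",
                                   frac_retained=frac)
    return EyePreprocessResult(
        False, "", t[sl].copy(), pos[sl], vel[sl], acc[sl], jerk[sl], frac
    )


def remove_saccades(
    jerk: np.ndarray,
    jerk_threshold: float = JERK_THRESHOLD_DEFAULT,
    pad: int = SACCADE_PAD_SAMPLES,
) -> np.ndarray:
    """Boolean mask of samples retained after jerk-threshold saccade removal.

    Samples whose |jerk| exceeds the threshold, plus ``pad`` samples on each
    side, are masked out (False).
    """
    j = np.asarray(jerk, dtype=float)
    bad = np.abs(j) > jerk_threshold
    if jerk_threshold <= 0:
        bad = np.ones_like(bad)
    if pad > 0 and bad.any():
        idx = np.flatnonzero(bad)
        for i in idx:
            bad[max(i - pad, 0) : i + pad + 1] = True
    return ~bad


@dataclass(frozen=True)
class EyeSweepSummary:
    """Mean eye velocity/speed over retained samples of the judged sweep."""

    ok: bool
    mean_velocity: float = math.nan
    mean_speed: float = math.nan
    n_valid: int = 0


def sweep_eye_summary(
    velocity: np.ndarray,
    valid: np.ndarray,
    start: int,
    end: int,
) -> EyeSweepSummary:
    """Summarize eye velocity on [start, end) using only valid samples;
    returns a typed 'no valid samples' outcome when none remain."""
    v = np.asarray(velocity, dtype=float)[start:end]
    m = np.asarray(valid, dtype=bool)[start:end]
    if not m.any():
        return EyeSweepSummary(False)
    return EyeSweepSummary(True, float(v[m].mean()),
                           float(np.abs(v[m]).mean()), int(m.sum()))
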