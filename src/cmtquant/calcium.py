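"""Calcium transient amplitudes from ROI intensity traces.

Rhod-3 fluorescence is averaged over an ROI per frame, smoothed with a
two-frame moving average, and each beat's amplitude is measured as the peak
value minus the preceding diastolic level. Because the dye is not
ratiometric, amplitudes are normalized to the mean center-ROI amplitude of
the control tissue from the same imaging session.

The diastolic level per beat is estimated as the median of the central half
of the preceding inter-peak interval: for a pulse train with a flat
diastole this estimator is unbiased under additive noise, unlike the raw
interval minimum, which is biased low by extreme-value statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .stack import ImageStack, ROISpec, crop_roi


@dataclasses.dataclass
class TraceResult:
    raw: np.ndarray
    smoothed: np.ndarray  # two-frame moving average, one frame shorter
    peak_frames: np.ndarray
    amplitude: float  # mean over beats of (peak - preceding diastolic level)
    per_beat_amplitudes: np.ndarray
    session: str | None = None
    normalized_amplitude: float | None = None


def roi_trace(stack: ImageStack, roi: ROISpec) -> np.ndarray:
    """Per-frame arithmetic mean intensity within an ROI."""
    cropped = crop_roi(stack, roi)
    return np.asarray(cropped.pixels, dtype=float).mean(axis=(1, 2))


def smooth_two_frame(raw: np.ndarray) -> np.ndarray:
    """Two-frame moving average: s[i] = (x[i] + x[i+1]) / 2."""
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("trace must have at least 2 frames for a two-frame average")
    return 0.5 * (x[:-1] + x[1:])


def amplitude(
    smoothed: np.ndarray, prominence_frac: float = 0.2
) -> tuple[float, np.ndarray, np.ndarray]:
    """Beat-averaged waveform amplitude of a smoothed trace.

    Peaks are detected with prominence 20% of the trace range (and a minimum
    spacing of half the median peak interval). Each beat contributes
    (peak value - diastolic level of the preceding inter-peak interval);
    the amplitude is their mean, or 0 for a trace with no beats. Returns
    (amplitude, per-beat amplitudes, peak frames).
    """
    x = np.asarray(smoothed, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    rng_ = float(np.ptp(x))
    if rng_ == 0:
        return 0.0, np.array([]), np.array([], int)
    peaks, _ = signal.find_peaks(x, prominence=prominence_frac * rng_)
    if len(peaks) >= 2:
        spacing = max(1, int(np.median(np.diff(peaks)) // 2))
        peaks, _ = signal.find_peaks(x, prominence=prominence_frac * rng_, distance=spacing)
    if len(peaks) == 0:
        return 0.0, np.array([]), np.array([], int)

    amps = []
    for i, p in enumerate(peaks):
        start = peaks[i - 1] if i > 0 else 0
        # central half of the preceding inter-peak interval: diastole for
        # any pulse occupying less than ~half the beat on each side
        q = (p - start) // 4
        lo, hi = start + q, p - q
        if hi <= lo:
            lo, hi = start, p
        diastolic = float(np.median(x[lo:hi])) if hi > lo else float(x[start])
        amps.append(x[p] - diastolic)
    amps = np.asarray(amps)
    return float(amps.mean()), amps, peaks


def analyze_trace(raw: np.ndarray, session: str | None = None) -> TraceResult:
    """Smooth a raw ROI trace and measure its beat amplitude."""
    smoothed = smooth_two_frame(raw)
    amp, per_beat, peaks = amplitude(smoothed)
    return TraceResult(
        raw=np.asarray(raw, float),
        smoothed=smoothed,
        peak_frames=peaks,
        amplitude=amp,
        per_beat_amplitudes=per_beat,
        session=session,
    )


def normalize_to_control(
    results: list[TraceResult], control_center_amplitudes: list[float], session: str | None = None
) -> list[TraceResult]:
    """Normalize amplitudes to the session's control-center mean amplitude.

    All traces and control amplitudes must come from the same imaging
    session; results carrying a different session tag raise.
    """
    if not control_center_amplitudes:
        raise ValueError("no control-center amplitudes supplied")
    control_mean = float(np.mean(control_center_amplitudes))
    if not (control_mean > 0):
        raise ValueError("control-center mean amplitude must be positive")
    out = []
    for r in results:
        if session is not None and r.session is not None and r.session != session:
            raise ValueError(
                f"trace from session {r.session!r} cannot be normalized with "
                f"session {session!r} controls"
            )
        out.append(dataclasses.replace(r, normalized_amplitude=r.amplitude / control_mean))
    return out
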