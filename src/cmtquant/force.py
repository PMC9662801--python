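"""Twitch force and resting tension from micropillar cap tracking.

The microtissue spans two flexible pillars; its contraction deflects the
pillar caps, and force follows Hooke's law with the measured spring
constant (2.68 uN/um). Cap positions are tracked per frame by upsampled
cross-correlation of a cap template against the first frame, giving
sub-pixel deflections along the pillar-to-pillar (x) axis. The force trace
is summarised into a diastolic baseline, a beat-averaged twitch force
(peak - baseline), contraction kinetics, and — across imaging days — the
twitch normalized to the pre-injury day and the change in resting tension.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal
from skimage import registration

from .stack import ImageStack


@dataclasses.dataclass
class PillarTrack:
    """Per-frame cap centres for the two pillars, (x, y) px."""

    centers_xy: np.ndarray  # (T, 2 pillars, 2)
    rest_xy: np.ndarray  # (2, 2) rest reference per pillar
    pixel_scale_um_per_px: float

    @property
    def deflection_um(self) -> np.ndarray:
        """(T, 2): |x - x_rest| along the pillar axis, in um."""
        dx = self.centers_xy[:, :, 0] - self.rest_xy[None, :, 0]
        return np.abs(dx) * self.pixel_scale_um_per_px


@dataclasses.dataclass
class TwitchSummary:
    baseline_uN: float
    twitch_force_uN: float | None  # None when no beats are detected
    n_beats: int
    peak_frames: np.ndarray
    time_to_peak_s: float | None
    time_to_half_relaxation_s: float | None


def track_pillars(
    stack: ImageStack,
    initial_centers_xy: np.ndarray,
    template_radius_px: int = 30,
    min_correlation: float = 0.2,
) -> PillarTrack:
    """Track both pillar caps through a time-lapse video.

    A square template of half-size ``template_radius_px`` is cut around each
    cap in frame 0 and registered into every later frame by Fourier
    cross-correlation with 100x sub-pixel upsampling. A normalised
    correlation below ``min_correlation`` raises a tracking-lost error
    naming the frame.

    The rest reference defaults to the diastolic plateau position along x
    (see :func:`diastolic_reference`); pass the track to downstream force
    conversion after setting ``rest_xy`` explicitly if an unloaded-pillar
    frame is available.
    """
    if stack.axes != "t":
        raise ValueError("track_pillars expects a time-lapse stack")
    centers0 = np.asarray(initial_centers_xy, dtype=float)
    if centers0.shape != (2, 2):
        raise ValueError("expected initial centres for exactly 2 pillars as (2, 2) (x, y)")
    frames = np.asarray(stack.pixels, dtype=float)
    T, h, w = frames.shape
    r = template_radius_px

    templates = []
    corners = []
    for cx, cy in centers0:
        x0, y0 = int(round(cx)) - r, int(round(cy)) - r
        if x0 < 0 or y0 < 0 or x0 + 2 * r + 1 > w or y0 + 2 * r + 1 > h:
            raise ValueError("template window around a cap extends outside the frame")
        templates.append(frames[0, y0 : y0 + 2 * r + 1, x0 : x0 + 2 * r + 1])
        corners.append((x0, y0))

    centers = np.empty((T, 2, 2))
    centers[0] = centers0
    for p in range(2):
        x0, y0 = corners[p]
        tmpl = templates[p]
        for t in range(1, T):
            win = frames[t, y0 : y0 + 2 * r + 1, x0 : x0 + 2 * r + 1]
            shift, error, _ = registration.phase_cross_correlation(
                tmpl, win, upsample_factor=100, normalization=None
            )
            # `error` ~ sqrt(1 - correlation^2); guard against lost caps
            if 1.0 - min(error, 1.0) ** 2 < min_correlation**2:
                raise ValueError(f"pillar {p} tracking lost at frame {t} (low correlation)")
            # returned shift registers the window back onto the template,
            # i.e. minus the cap displacement
            centers[t, p, 0] = centers0[p, 0] - shift[1]
            centers[t, p, 1] = centers0[p, 1] - shift[0]

    track = PillarTrack(
        centers_xy=centers,
        rest_xy=centers0.copy(),
        pixel_scale_um_per_px=stack.pixel_scale_um_per_px,
    )
    track.rest_xy = diastolic_reference(track)
    return track


def diastolic_reference(track: PillarTrack) -> np.ndarray:
    """Estimate each cap's rest position as its diastolic plateau centre.

    Diastolic frames are those whose x position is within 25% of the motion
    range of the extreme resting-side position; their mean is the reference.
    Pillars deflect toward the tissue, so the resting side is the extreme
    position farthest from the mean of the other pillar.
    """
    rest = np.empty((2, 2))
    for p in range(2):
        x = track.centers_xy[:, p, 0]
        other = track.centers_xy[:, 1 - p, 0].mean()
        # rest = extreme x farthest from the opposing pillar
        lo, hi = x.min(), x.max()
        rest_x = lo if abs(lo - other) > abs(hi - other) else hi
        rng_ = hi - lo
        diastolic = np.abs(x - rest_x) <= 0.25 * rng_ if rng_ > 0 else np.ones_like(x, bool)
        # median, not mean: the diastolic band may include a few ramp frames
        rest[p, 0] = np.median(x[diastolic])
        rest[p, 1] = np.median(track.centers_xy[diastolic, p, 1])
    return rest


def deflection_to_force(deflection_um: np.ndarray, k_uN_per_um: float) -> np.ndarray:
    """Hooke's law per pillar: force = k * deflection (uN)."""
    d = np.asarray(deflection_um, dtype=float)
    if k_uN_per_um <= 0:
        raise ValueError("spring constant must be positive")
    if (d < -1e-12).any():
        raise ValueError("deflections must be nonnegative (reference to true rest first)")
    return k_uN_per_um * d


def tissue_force_trace(track: PillarTrack, k_uN_per_um: float) -> np.ndarray:
    """Per-frame tissue force: mean of the two pillar forces.

    In a two-post tissue the pillar forces are equal and opposite; their
    mean is reported as the tissue's force.
    """
    forces = deflection_to_force(track.deflection_um, k_uN_per_um)
    return forces.mean(axis=1)


def _baseline(trace: np.ndarray) -> tuple[float, np.ndarray]:
    """Diastolic baseline: median of frames in the lowest quartile of the range.

    The median is insensitive to the few systolic ramp frames that fall
    inside the band while remaining unbiased on the flat diastolic plateau.
    """
    rng_ = float(np.ptp(trace))
    if rng_ == 0:
        return float(trace.mean()), np.ones_like(trace, bool)
    diastolic = trace <= trace.min() + 0.25 * rng_
    return float(np.median(trace[diastolic])), diastolic


def twitch_metrics(
    force_trace_uN: np.ndarray,
    frame_rate_fps: float,
    prominence_frac: float = 0.2,
    onset_frac: float = 0.1,
    relaxation_frac: float = 0.5,
) -> TwitchSummary:
    """Beat-averaged twitch force and contraction kinetics from a force trace.

    Baseline is the mean of the diastolic plateau (lowest quartile of the
    trace range). Twitch force is the mean over detected beats of
    (peak - baseline). Time-to-peak runs from the beat onset (force crossing
    baseline + ``onset_frac`` * twitch) to the peak; relaxation time runs
    from the peak to ``relaxation_frac`` decay of the twitch. A trace with
    no detectable beats reports baseline only.
    """
    x = np.asarray(force_trace_uN, dtype=float)
    baseline, _ = _baseline(x)
    rng_ = float(np.ptp(x))
    peaks = np.array([], int)
    if rng_ > 0:
        peaks, _ = signal.find_peaks(x, prominence=prominence_frac * rng_)
        if len(peaks) >= 2:
            spacing = max(1, int(np.median(np.diff(peaks)) // 2))
            peaks, _ = signal.find_peaks(x, prominence=prominence_frac * rng_, distance=spacing)
    if len(peaks) == 0:
        return TwitchSummary(baseline, None, 0, peaks, None, None)

    amplitudes = x[peaks] - baseline
    twitch = float(amplitudes.mean())
    ttp, rel = [], []
    for i, p in enumerate(peaks):
        onset_level = baseline + onset_frac * (x[p] - baseline)
        relax_level = baseline + relaxation_frac * (x[p] - baseline)
        start = peaks[i - 1] if i > 0 else 0
        seg = x[start : p + 1]
        below = np.flatnonzero(seg <= onset_level)
        if below.size:
            ttp.append((p - (start + below[-1])) / frame_rate_fps)
        stop = peaks[i + 1] if i + 1 < len(peaks) else len(x)
        seg = x[p:stop]
        under = np.flatnonzero(seg <= relax_level)
        if under.size:
            rel.append(under[0] / frame_rate_fps)
    return TwitchSummary(
        baseline_uN=baseline,
        twitch_force_uN=twitch,
        n_beats=len(peaks),
        peak_frames=peaks,
        time_to_peak_s=float(np.mean(ttp)) if ttp else None,
        time_to_half_relaxation_s=float(np.mean(rel)) if rel else None,
    )


def normalize_to_baseline_day(
    twitch_by_day: dict[str, float], reference_day: str, tissue: str = ""
) -> dict[str, float]:
    """Normalize a tissue's twitch forces to its pre-injury reference day."""
    if reference_day not in twitch_by_day:
        raise ValueError(f"tissue {tissue or '?'}: no twitch measurement for reference day {reference_day}")
    ref = twitch_by_day[reference_day]
    if not (ref > 0):
        raise ValueError(f"tissue {tissue or '?'}: reference-day twitch must be positive, got {ref}")
    return {day: v / ref for day, v in twitch_by_day.items()}


def resting_tension_change(
    baseline_by_day: dict[str, float], reference_day: str
) -> dict[str, float]:
    """Change in resting tension vs the pre-injury baseline, per day (uN)."""
    if reference_day not in baseline_by_day:
        raise ValueError(f"missing pre-injury baseline measurement for day {reference_day}")
    ref = baseline_by_day[reference_day]
    return {day: v - ref for day, v in baseline_by_day.items()}


def beating_is_synchronous(
    peaks_a: np.ndarray, peaks_b: np.ndarray, beat_period_frames: float, tolerance_frac: float = 0.25
) -> bool:
    """Whether the two pillars' beat peaks align within 25% of the period.

    Asynchronously beating tissues are flagged and excluded from twitch
    statistics.
    """
    a, b = np.asarray(peaks_a, float), np.asarray(peaks_b, float)
    if a.size == 0 or b.size == 0 or a.size != b.size:
        return False
    return bool(np.all(np.abs(a - b) <= tolerance_frac * beat_period_frames))
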