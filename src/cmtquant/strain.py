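"""Regional Green-Lagrange strain from feature tracking in tissue videos.

The tissue's spontaneous beat is quantified per rectangular ROI: Shi-Tomasi
corner points are detected, tracked with an iterative pyramidal
Lucas-Kanade scheme, and the per-ROI average deformation gradient F is fit
in least squares from the tracked displacements. The Green-Lagrange tensor
E = (F^T F - I)/2 then gives the strain; E_xx is its component along the
pillar-to-pillar axis (image x), negative in contraction.

Time is partitioned into beat periods from the mean absolute corner
displacement trace: peaks are detected, temporal reference points sit
halfway between consecutive peaks, and each reference-to-reference span is
one period whose first frame is the strain reference. n peaks give n-1
reference points and n-2 periods. The per-video output is the signed
maximum-magnitude E_xx per period, averaged over periods, for each ROI.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, signal
from skimage import feature, transform

from .stack import ImageStack, ROISpec


@dataclasses.dataclass(frozen=True)
class StrainConfig:
    """Tracking parameters. The algorithms are standard; these defaults are
    this package's (logged, configurable) choices."""

    max_corners: int = 200
    corner_quality: float = 0.01  # relative threshold on Shi-Tomasi response
    min_distance_px: int = 5
    window_px: int = 21  # LK integration window (odd)
    pyramid_levels: int = 3
    fb_threshold_px: float = 1.0  # forward-backward validity cutoff
    peak_prominence_frac: float = 0.2  # of displacement-trace range
    upsample_factor: int = 1  # optional integer image upsampling, off by default


@dataclasses.dataclass
class TrackedPoints:
    """Reference positions and per-frame tracked positions, (x, y) in px."""

    reference_xy: np.ndarray  # (N, 2)
    positions_xy: np.ndarray  # (T, N, 2)
    valid: np.ndarray  # (T, N) bool


@dataclasses.dataclass(frozen=True)
class TemporalPartition:
    peak_frames: np.ndarray
    reference_frames: np.ndarray  # halfway between consecutive peaks (floored)
    periods: list[tuple[int, int]]  # (start_frame, end_frame) spans

    @property
    def n_periods(self) -> int:
        return len(self.periods)


# ---------------------------------------------------------------------------
# Corner detection


def detect_corners(
    frame: np.ndarray,
    max_points: int = 200,
    quality: float = 0.01,
    min_distance_px: int = 5,
    exclude_border_px: int = 12,
) -> np.ndarray:
    """Shi-Tomasi corners of one frame as (x, y) positions, strongest first.

    The minimum-eigenvalue corner response is thresholded at ``quality``
    times its maximum; peaks are non-max suppressed at ``min_distance_px``.
    Raises if fewer than 3 corners are found (a strain fit needs at least 3
    non-collinear points).
    """
    frame = np.asarray(frame, dtype=float)
    response = feature.corner_shi_tomasi(frame)
    peaks = feature.corner_peaks(
        response,
        min_distance=min_distance_px,
        threshold_rel=quality,
        num_peaks=max_points,
        exclude_border=exclude_border_px,
    )
    if len(peaks) < 3:
        raise ValueError(
            f"only {len(peaks)} corners found; the image texture is too poor to "
            "estimate strain (need >= 3 trackable points)"
        )
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


# ---------------------------------------------------------------------------
# Sparse iterative pyramidal Lucas-Kanade


def _sample(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear sample of img at (x, y) positions of arbitrary shape."""
    coords = np.stack([xy[..., 1].ravel(), xy[..., 0].ravel()])
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest").reshape(xy.shape[:-1])


def _lk_refine(
    template: np.ndarray,
    target: np.ndarray,
    pts_t: np.ndarray,
    guess: np.ndarray,
    window: int,
    n_iter: int = 20,
    eps: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """One-level iterative LK: refine target positions for all points at once.

    Uses the template-gradient (inverse additive) formulation: the spatial
    gradient matrix G is built once per point from the template window and
    reused across iterations.
    """
    half = window // 2
    oy, ox = np.mgrid[-half : half + 1, -half : half + 1]
    offsets = np.stack([ox.ravel(), oy.ravel()], axis=-1)  # (W2, 2)

    win_t = pts_t[:, None, :] + offsets[None]  # (N, W2, 2)
    T = _sample(template, win_t)
    gy_img, gx_img = np.gradient(template)
    gx = _sample(gx_img, win_t)
    gy = _sample(gy_img, win_t)
    G = np.empty((len(pts_t), 2, 2))
    G[:, 0, 0] = np.sum(gx * gx, axis=1)
    G[:, 0, 1] = G[:, 1, 0] = np.sum(gx * gy, axis=1)
    G[:, 1, 1] = np.sum(gy * gy, axis=1)
    ok = np.linalg.cond(G) < 1e8
    Ginv = np.linalg.inv(np.where(ok[:, None, None], G, np.eye(2)))

    pos = guess.copy()
    active = ok.copy()
    for _ in range(n_iter):
        if not active.any():
            break
        win_i = pos[active, None, :] + offsets[None]
        I = _sample(target, win_i)
        diff = T[active] - I
        b = np.stack([np.sum(gx[active] * diff, axis=1), np.sum(gy[active] * diff, axis=1)], axis=-1)
        step = np.einsum("nij,nj->ni", Ginv[active], b)
        pos[active] += step
        still = np.linalg.norm(step, axis=1) >= eps
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return pos, ok


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 32:
            break
        pyr.append(transform.pyramid_reduce(pyr[-1], downscale=2, preserve_range=True))
    return pyr


def lucas_kanade(
    reference: np.ndarray,
    target: np.ndarray,
    pts_xy: np.ndarray,
    init_xy: np.ndarray | None = None,
    window_px: int = 21,
    pyramid_levels: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Track sparse points from a reference image into a target image.

    Coarse-to-fine refinement over Gaussian pyramids; returns the target
    positions and a per-point success flag (ill-conditioned gradient
    windows are flagged out).
    """
    pts_xy = np.asarray(pts_xy, dtype=float)
    init = pts_xy.copy() if init_xy is None else np.asarray(init_xy, dtype=float).copy()
    pyr_ref = _pyramid(reference, pyramid_levels)
    pyr_tgt = _pyramid(target, pyramid_levels)
    levels = min(len(pyr_ref), len(pyr_tgt))

    scale = 2.0 ** (levels - 1)
    disp = (init - pts_xy) / scale
    ok_all = np.ones(len(pts_xy), dtype=bool)
    for lvl in range(levels - 1, -1, -1):
        s = 2.0**lvl
        pts_l = pts_xy / s
        pos, ok = _lk_refine(pyr_ref[lvl], pyr_tgt[lvl], pts_l, pts_l + disp, window_px)
        ok_all &= ok
        disp = pos - pts_l
        if lvl > 0:
            disp = disp * 2.0
    return pts_xy + disp, ok_all


def track_points(
    stack: ImageStack,
    reference_xy: np.ndarray,
    cfg: StrainConfig | None = None,
) -> TrackedPoints:
    """Track points from the stack's first frame through every later frame.

    Each frame is registered against the first frame's template windows,
    initialised from the previous frame's solution; a forward-backward
    re-track larger than ``fb_threshold_px`` invalidates a point from that
    frame on.
    """
    cfg = cfg or StrainConfig()
    reference_xy = np.asarray(reference_xy, dtype=float)
    if len(reference_xy) < 3:
        raise ValueError("need at least 3 reference points")
    T = stack.n_planes
    positions = np.empty((T, len(reference_xy), 2))
    valid = np.ones((T, len(reference_xy)), dtype=bool)
    positions[0] = reference_xy

    ref_img = np.asarray(stack[0], dtype=float)
    prev = reference_xy
    for t in range(1, T):
        cur_img = np.asarray(stack[t], dtype=float)
        pos, ok = lucas_kanade(
            ref_img, cur_img, reference_xy, init_xy=prev,
            window_px=cfg.window_px, pyramid_levels=cfg.pyramid_levels,
        )
        back, ok_b = lucas_kanade(
            cur_img, ref_img, pos, init_xy=reference_xy,
            window_px=cfg.window_px, pyramid_levels=cfg.pyramid_levels,
        )
        fb_err = np.linalg.norm(back - reference_xy, axis=1)
        valid[t] = valid[t - 1] & ok & ok_b & (fb_err <= cfg.fb_threshold_px)
        positions[t] = pos
        prev = pos
    if not valid[-1].any():
        raise ValueError("all points lost during tracking")
    return TrackedPoints(reference_xy=reference_xy, positions_xy=positions, valid=valid)


# ---------------------------------------------------------------------------
# Beat partitioning


def partition_beats(
    displacement_trace: np.ndarray,
    prominence_frac: float = 0.2,
) -> TemporalPartition:
    """Partition a beat video into temporal periods from its displacement trace.

    Peaks are found with a prominence of ``prominence_frac`` times the trace
    range, then re-found with a minimum spacing of half the median peak
    interval. Reference frames are floor((p_i + p_{i+1})/2); consecutive
    reference frames bound the periods. Fewer than 3 peaks yield zero
    periods rather than an error.
    """
    x = np.asarray(displacement_trace, dtype=float)
    if x.size < 3:
        raise ValueError("displacement trace must have at least 3 frames")
    rng_ = float(np.ptp(x))
    if rng_ == 0:
        return TemporalPartition(np.array([], int), np.array([], int), [])
    prominence = prominence_frac * rng_
    peaks, _ = signal.find_peaks(x, prominence=prominence)
    if len(peaks) >= 2:
        min_spacing = max(1, int(np.median(np.diff(peaks)) // 2))
        peaks, _ = signal.find_peaks(x, prominence=prominence, distance=min_spacing)
    refs = ((peaks[:-1] + peaks[1:]) // 2).astype(int) if len(peaks) >= 2 else np.array([], int)
    periods = [(int(refs[i]), int(refs[i + 1])) for i in range(len(refs) - 1)]
    return TemporalPartition(peak_frames=np.asarray(peaks, int), reference_frames=refs, periods=periods)


def displacement_trace(tracked: TrackedPoints) -> np.ndarray:
    """Mean absolute displacement of valid points per frame, px."""
    disp = np.linalg.norm(tracked.positions_xy - tracked.reference_xy[None], axis=2)
    masked = np.where(tracked.valid, disp, np.nan)
    return np.nanmean(masked, axis=1)


# ---------------------------------------------------------------------------
# Deformation gradient and strain


def fit_deformation_gradient(reference_xy: np.ndarray, current_xy: np.ndarray) -> np.ndarray:
    """Least-squares average deformation gradient of an ROI.

    Minimises sum_i ||(x_i - xbar) - F (X_i - Xbar)||^2 over centred
    coordinates (X reference, x current); translation is absorbed by the
    centring. Requires >= 3 non-collinear point pairs.
    """
    X = np.asarray(reference_xy, dtype=float)
    x = np.asarray(current_xy, dtype=float)
    if X.shape != x.shape or X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("point arrays must both be (N, 2)")
    if len(X) < 3:
        raise ValueError("need at least 3 point pairs to fit F")
    Xc = X - X.mean(axis=0)
    xc = x - x.mean(axis=0)
    A = Xc.T @ Xc
    if np.linalg.matrix_rank(A, tol=1e-9 * np.trace(A)) < 2:
        raise ValueError("degenerate (collinear) reference configuration")
    return (xc.T @ Xc) @ np.linalg.inv(A)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I)/2; symmetric by construction."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (F.T @ F - np.eye(2))


def period_strain(E_xx_series: np.ndarray) -> float:
    """Signed maximum-magnitude E_xx over a period's frames.

    Contractile strain is negative, so the maximum refers to maximum
    magnitude with the sign preserved (a passively stretched injured region
    reports positive strain).
    """
    e = np.asarray(E_xx_series, dtype=float)
    if e.size < 1:
        raise ValueError("empty strain series")
    return float(e[np.argmax(np.abs(e))])


# ---------------------------------------------------------------------------
# Full-video analysis


@dataclasses.dataclass
class PeriodStrain:
    roi_role: str
    period: tuple[int, int]
    E_xx_series: np.ndarray
    E_series: list[np.ndarray]  # per-frame 2x2 tensors
    max_magnitude_E_xx: float


@dataclasses.dataclass
class VideoStrainResult:
    partition: TemporalPartition
    per_period: list[PeriodStrain]
    mean_E_xx: dict[str, float]  # roi role -> mean over periods
    no_beats: bool = False


def _roi_corners(stack: ImageStack, roi: ROISpec, frame: int, cfg: StrainConfig) -> np.ndarray:
    """Corners detected within an ROI of a given frame, in full-frame coords."""
    rows, cols = roi.to_pixels(stack.pixel_scale_um_per_px)
    sub = np.asarray(stack[frame], dtype=float)[rows, cols]
    pts = detect_corners(
        sub,
        max_points=cfg.max_corners,
        quality=cfg.corner_quality,
        min_distance_px=cfg.min_distance_px,
        exclude_border_px=cfg.min_distance_px,
    )
    return pts + np.array([cols.start, rows.start], dtype=float)


def _upsampled(stack: ImageStack, factor: int) -> ImageStack:
    if factor == 1:
        return stack
    planes = np.stack(
        [ndimage.zoom(p, factor, order=1) for p in np.asarray(stack.pixels, dtype=float)]
    )
    return ImageStack(planes, axes=stack.axes, pixel_scale_um_per_px=stack.pixel_scale_um_per_px / factor)


def analyze_video(
    stack: ImageStack,
    rois: dict[str, ROISpec],
    cfg: StrainConfig | None = None,
) -> VideoStrainResult:
    """Per-ROI mean maximum-magnitude E_xx over all temporal periods.

    The beat is first located globally: corners from every ROI are tracked
    across the whole video against its first frame and the mean absolute
    displacement trace is partitioned into periods. Then, for each period
    and ROI independently, corners are re-detected at the period's first
    frame and tracked through the period; each frame's average F (relative
    to the period's first frame) gives E, and the period contributes its
    signed max-magnitude E_xx. A video with fewer than 3 displacement peaks
    reports no beats rather than failing.
    """
    cfg = cfg or StrainConfig()
    stack = _upsampled(stack, cfg.upsample_factor)

    # global displacement trace for beat detection (first frame as reference)
    traces = []
    for roi in rois.values():
        pts = _roi_corners(stack, roi, frame=0, cfg=cfg)
        tracked = track_points(stack, pts, cfg)
        traces.append(displacement_trace(tracked))
    partition = partition_beats(np.mean(traces, axis=0), cfg.peak_prominence_frac)
    if partition.n_periods == 0:
        return VideoStrainResult(partition=partition, per_period=[], mean_E_xx={}, no_beats=True)

    per_period: list[PeriodStrain] = []
    for role, roi in rois.items():
        for (start, end) in partition.periods:
            sub = ImageStack(
                stack.pixels[start : end + 1],
                axes="t",
                pixel_scale_um_per_px=stack.pixel_scale_um_per_px,
            )
            pts = _roi_corners(sub, roi, frame=0, cfg=cfg)
            tracked = track_points(sub, pts, cfg)
            E_xx = np.zeros(sub.n_planes)
            tensors = [np.zeros((2, 2))]
            for t in range(1, sub.n_planes):
                keep = tracked.valid[t]
                F = fit_deformation_gradient(
                    tracked.reference_xy[keep], tracked.positions_xy[t][keep]
                )
                E = green_lagrange(F)
                tensors.append(E)
                E_xx[t] = E[0, 0]
            per_period.append(
                PeriodStrain(
                    roi_role=role,
                    period=(start, end),
                    E_xx_series=E_xx,
                    E_series=tensors,
                    max_magnitude_E_xx=period_strain(E_xx),
                )
            )
    mean_E_xx = {
        role: float(np.mean([p.max_magnitude_E_xx for p in per_period if p.roi_role == role]))
        for role in rois
    }
    return VideoStrainResult(partition=partition, per_period=per_period, mean_E_xx=mean_E_xx)
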