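"""Synthetic fixtures with analytic ground truth for every pipeline stage.

Each generator emulates one acquisition the pipeline quantifies and returns
the rendered pixels (or trace, or curve) together with a ground-truth table
sufficient to score the downstream analysis with no other information:

- :func:`make_deforming_video` — textured tissue warped by prescribed
  time-varying affine maps (known Green-Lagrange strain per ROI per frame);
- :func:`make_pillar_video` — two dark pillar caps translating with a twitch
  waveform (known deflection and force per frame);
- :func:`make_fibril_stack` — bright myofibril-like bars with PSF blur and
  speckle (known per-bar lengths);
- :func:`make_calcium_trace` — periodic pulse train with additive noise
  (known amplitude);
- :func:`make_hertz_curve` — spherical-indenter loading curves (known
  Young's modulus).

All beats use a raised-cosine pulse occupying a duty fraction of the beat
period, so every cycle has a genuine diastolic plateau between pulses.
Generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .hertz import hertz_force
from .stack import ImageStack, ROISpec


def beat_waveform(n_frames: int, period_frames: int, duty: float = 0.6) -> np.ndarray:
    """Raised-cosine pulse train, one pulse per beat period, range [0, 1].

    Pulse ``k`` spans ``[k*P + (P-W)/2, k*P + (P+W)/2]`` with ``W = duty*P``,
    peaking at ``k*P + P/2``; outside pulses the waveform is exactly zero, so
    frames at integer multiples of the period form a true diastolic baseline.
    """
    if not (0 < duty < 1):
        raise ValueError(f"duty must be in (0, 1), got {duty}")
    if period_frames < 4:
        raise ValueError("beat period must be at least 4 frames")
    t = np.arange(n_frames, dtype=float)
    phase = np.mod(t, period_frames)  # position within the current beat
    width = duty * period_frames
    lo = (period_frames - width) / 2.0
    inside = (phase >= lo) & (phase <= lo + width)
    w = np.zeros(n_frames)
    w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (phase[inside] - lo) / width))
    return w


def band_pass_texture(
    shape: tuple[int, int],
    seed: int,
    fine_sd: float = 1.5,
    coarse_sd: float = 6.0,
) -> np.ndarray:
    """Band-pass filtered white noise: dense, well-conditioned corners.

    Difference of two Gaussian blurs of the same white-noise field, rescaled
    to mean 128 / sd 30 and clipped to [0, 255]. The smoothness set by
    ``fine_sd`` keeps bilinear interpolation of the warped frames accurate.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    band = ndimage.gaussian_filter(noise, fine_sd) - ndimage.gaussian_filter(noise, coarse_sd)
    band = (band - band.mean()) / band.std()
    return np.clip(128.0 + 30.0 * band, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Deforming tissue video


@dataclasses.dataclass(frozen=True)
class ROIDeformation:
    """Prescribed peak deformation applied about one ROI's centre."""

    roi: ROISpec
    peak_E_xx: float
    peak_E_yy: float = 0.0
    peak_rotation_rad: float = 0.0
    peak_translation_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if abs(self.peak_E_xx) >= 0.2 or abs(self.peak_E_yy) >= 0.2:
            raise ValueError("prescribed |E| must be < 0.2 for a well-posed warp")


@dataclasses.dataclass(frozen=True)
class DeformationScenario:
    base_texture_seed: int
    n_frames: int
    beat_period_frames: int
    rois: tuple[ROIDeformation, ...]
    image_shape_px: tuple[int, int] = (160, 160)
    duty: float = 0.6

    def __post_init__(self) -> None:
        if self.n_frames < max(3, 2 * self.beat_period_frames):
            raise ValueError("need n_frames >= 2 * beat_period_frames (at least two beats)")
        if not self.rois:
            raise ValueError("scenario needs at least one ROI")


def _deformation_gradient(E_xx: float, E_yy: float, theta: float) -> np.ndarray:
    """F = R(theta) @ diag(sqrt(1+2E_xx), sqrt(1+2E_yy)).

    Green-Lagrange strain of this map is exactly diag(E_xx, E_yy): the
    rotation drops out of (F^T F - I)/2.
    """
    lam_x = np.sqrt(1.0 + 2.0 * E_xx)
    lam_y = np.sqrt(1.0 + 2.0 * E_yy)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]]) @ np.diag([lam_x, lam_y])


def _blend_weight(shape: tuple[int, int], rows: slice, cols: slice, inner: int, outer: int) -> np.ndarray:
    """1 inside the ROI grown by ``inner`` px, smoothstep to 0 by ``outer`` px."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = np.maximum(np.maximum(rows.start - yy, yy - (rows.stop - 1)), 0)
    dx = np.maximum(np.maximum(cols.start - xx, xx - (cols.stop - 1)), 0)
    d = np.hypot(dx, dy)
    u = np.clip((d - inner) / max(outer - inner, 1), 0.0, 1.0)
    return 1.0 - u * u * (3.0 - 2.0 * u)  # smoothstep falloff


def make_deforming_video(
    scn: DeformationScenario,
    scale_um_per_px: float,
    blend_inner_px: int = 8,
    blend_outer_px: int = 32,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a texture video deforming under prescribed per-ROI affine maps.

    Inside each ROI (plus ``blend_inner_px`` margin) frame ``t`` is exactly
    the base texture pushed forward by ``F(t)`` about the ROI centre, where
    the Green-Lagrange strain of ``F(t)`` equals the prescribed peak strain
    scaled by the raised-cosine beat waveform. Between ROIs the displacement
    fields are smoothly blended; scenarios whose blend regions overlap are
    rejected so the ground truth stays exact where it is scored.

    Returns the video and a per-frame, per-ROI table with columns
    ``frame, roi_role, E_xx, E_yy, waveform``.
    """
    shape = scn.image_shape_px
    texture = band_pass_texture(shape, scn.base_texture_seed)
    w = beat_waveform(scn.n_frames, scn.beat_period_frames, scn.duty)

    roi_px = [rd.roi.to_pixels(scale_um_per_px) for rd in scn.rois]
    weights = [
        _blend_weight(shape, rows, cols, blend_inner_px, blend_outer_px)
        for rows, cols in roi_px
    ]
    if len(weights) > 1:
        overlap = np.sum([wt > 0 for wt in weights], axis=0) > 1
        if overlap.any():
            raise ValueError("ROI blend regions overlap; ground truth would be inexact")
    centers = [
        np.array([(cols.start + cols.stop - 1) / 2.0, (rows.start + rows.stop - 1) / 2.0])
        for rows, cols in roi_px
    ]

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    frames = np.empty((scn.n_frames, *shape), dtype=np.float32)
    records = []
    for t in range(scn.n_frames):
        sx = xx.copy()
        sy = yy.copy()
        for rd, wt, c in zip(scn.rois, weights, centers):
            F = _deformation_gradient(
                rd.peak_E_xx * w[t], rd.peak_E_yy * w[t], rd.peak_rotation_rad * w[t]
            )
            Finv = np.linalg.inv(F)
            tx = rd.peak_translation_px[0] * w[t]
            ty = rd.peak_translation_px[1] * w[t]
            # inverse of the forward map x' = c + F (x - c) + translation
            ux, uy = xx - c[0] - tx, yy - c[1] - ty
            dx = Finv[0, 0] * ux + Finv[0, 1] * uy + c[0] - xx
            dy = Finv[1, 0] * ux + Finv[1, 1] * uy + c[1] - yy
            sx += wt * dx
            sy += wt * dy
            records.append(
                {
                    "frame": t,
                    "roi_role": rd.roi.role,
                    "E_xx": rd.peak_E_xx * w[t],
                    "E_yy": rd.peak_E_yy * w[t],
                    "waveform": w[t],
                }
            )
        frames[t] = ndimage.map_coordinates(texture, [sy, sx], order=1, mode="reflect")

    stack = ImageStack(pixels=frames, axes="t", pixel_scale_um_per_px=scale_um_per_px)
    return stack, pd.DataFrame.from_records(records)


def warp_points(points_xy: np.ndarray, F: np.ndarray, center_xy: np.ndarray) -> np.ndarray:
    """Forward map of feature points under F about a centre (analytic oracle)."""
    pts = np.asarray(points_xy, dtype=float)
    c = np.asarray(center_xy, dtype=float)
    return (pts - c) @ F.T + c


# ---------------------------------------------------------------------------
# Pillar twitch video


@dataclasses.dataclass(frozen=True)
class TwitchScenario:
    peak_deflection_um: float
    baseline_deflection_um: float = 0.0
    beat_period_frames: int = 40
    n_frames: int = 60
    noise_sd: float = 0.0
    image_shape_px: tuple[int, int] = (128, 256)
    cap_radius_px: float = 20.0
    duty: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_deflection_um < 0 or self.baseline_deflection_um < 0:
            raise ValueError("deflections must be nonnegative")


def _render_disc(shape, cx, cy, radius, edge_sd=1.5, fg=30.0, bg=200.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r = np.hypot(xx - cx, yy - cy)
    # smooth (error-function) edge profile so sub-pixel positions render
    # as near-exact translates of each other
    coverage = 0.5 * (1.0 + special.erf((radius - r) / (np.sqrt(2.0) * edge_sd)))
    return bg + (fg - bg) * coverage


def make_pillar_video(
    scn: TwitchScenario,
    spring_constant_uN_per_um: float,
    scale_um_per_px: float,
) -> tuple[ImageStack, pd.DataFrame]:
    """Two dark circular pillar caps on a bright background, twitching.

    Contraction pulls both caps toward the tissue centre along x: the left
    cap by ``+d(t)``, the right cap by ``-d(t)`` pixels, with
    ``d(t) = baseline + peak * waveform(t)`` in micrometres. The ground
    truth table lists, per frame, the true deflection, the force
    ``k * deflection``, and the analytic cap centres.
    """
    h, w = scn.image_shape_px
    defl_px = (
        scn.baseline_deflection_um
        + scn.peak_deflection_um * beat_waveform(scn.n_frames, scn.beat_period_frames, scn.duty)
    ) / scale_um_per_px
    cy = h / 2.0
    x_left_rest, x_right_rest = w * 0.25, w * 0.75
    if defl_px.max() >= w * 0.25 - scn.cap_radius_px - 4:
        raise ValueError("deflection pushes a cap out of frame")

    rng = np.random.default_rng(scn.seed)
    frames = np.empty((scn.n_frames, h, w), dtype=np.float32)
    records = []
    for t in range(scn.n_frames):
        xl = x_left_rest + defl_px[t]
        xr = x_right_rest - defl_px[t]
        img = _render_disc((h, w), xl, cy, scn.cap_radius_px)
        img += _render_disc((h, w), xr, cy, scn.cap_radius_px) - 200.0
        if scn.noise_sd > 0:
            img = img + rng.normal(0.0, scn.noise_sd, size=img.shape)
        frames[t] = np.clip(img, 0.0, None)
        d_um = defl_px[t] * scale_um_per_px
        records.append(
            {
                "frame": t,
                "deflection_um": d_um,
                "force_uN": spring_constant_uN_per_um * d_um,
                "x_left_px": xl,
                "x_right_px": xr,
                "y_px": cy,
            }
        )

    stack = ImageStack(pixels=frames, axes="t", pixel_scale_um_per_px=scale_um_per_px)
    return stack, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Fibril z-stack


@dataclasses.dataclass(frozen=True)
class Bar:
    """One myofibril-like bar: centre (x, y) in um, orientation, size in um.

    Bars are rendered as filled elongated ellipses so that the
    ellipse-equivalent major axis length reported by region properties
    equals ``length_um`` exactly for an ideal segmentation (a filled
    ellipse of major axis L has second-moment major axis L).
    """

    center_um: tuple[float, float]
    orientation_rad: float
    length_um: float
    width_um: float = 2.0


@dataclasses.dataclass(frozen=True)
class FibrilScenario:
    bars: tuple[Bar, ...]
    scale_um_per_px: float = 0.5
    image_shape_px: tuple[int, int] = (256, 256)
    n_slices: int = 3
    psf_sd_px: float = 1.0
    speckle_density: float = 0.0  # fraction of pixels hit by 1-px bright dots
    speckle_amplitude: float = 150.0
    seed: int = 0
    min_length_um: float = 6.0  # cutoff mirrored by the segmentation filter


def _bar_mask(shape, bar: Bar, scale: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    cx, cy = bar.center_um[0] / scale, bar.center_um[1] / scale
    c, s = np.cos(bar.orientation_rad), np.sin(bar.orientation_rad)
    u = c * (xx - cx) + s * (yy - cy)  # along-bar coordinate, px
    v = -s * (xx - cx) + c * (yy - cy)
    a = bar.length_um / scale / 2.0  # semi-major, px
    b = bar.width_um / scale / 2.0
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # ~1-px anti-aliased elliptical edge (distance approximated near the side)
    return np.clip(0.5 + (1.0 - rho) * b, 0.0, 1.0)


def make_fibril_stack(scn: FibrilScenario) -> tuple[ImageStack, float]:
    """Bright blurred bars on a dark background, with optional speckle.

    All slices share the same bars (independent speckle realisations per
    slice). The returned ground truth is the summed length of bars strictly
    longer than ``scn.min_length_um`` — the quantity the segmentation stage
    reports after its length filter.
    """
    shape = scn.image_shape_px
    h, w = shape
    masks = [_bar_mask(shape, bar, scn.scale_um_per_px) for bar in scn.bars]
    if masks:
        hard = [m > 0.5 for m in masks]
        if np.sum(hard, axis=0).max(initial=0) > 1:
            raise ValueError("bars overlap; scenario requires disjoint bars")
        for bar, m in zip(scn.bars, masks):
            edge = np.zeros_like(m, dtype=bool)
            edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
            if m[edge].max() > 0:
                raise ValueError(f"bar {bar} extends outside the image")
    base = 10.0 + 190.0 * (np.sum(masks, axis=0) if masks else np.zeros(shape))

    rng = np.random.default_rng(scn.seed)
    slices = np.empty((scn.n_slices, h, w), dtype=np.float32)
    for z in range(scn.n_slices):
        img = ndimage.gaussian_filter(base, scn.psf_sd_px)
        if scn.speckle_density > 0:
            n_dots = int(round(scn.speckle_density * h * w))
            ys = rng.integers(0, h, n_dots)
            xs = rng.integers(0, w, n_dots)
            img = img.copy()
            img[ys, xs] += scn.speckle_amplitude
        slices[z] = img

    truth = float(sum(b.length_um for b in scn.bars if b.length_um > scn.min_length_um))
    stack = ImageStack(pixels=slices, axes="z", pixel_scale_um_per_px=scn.scale_um_per_px)
    return stack, truth


# ---------------------------------------------------------------------------
# Calcium trace


def make_calcium_trace(
    amplitude: float,
    baseline: float,
    n_beats: int,
    period_frames: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
    duty: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Periodic raised-cosine calcium pulses plus Gaussian noise.

    The pulse width is ``duty * period_frames`` and must be at least 10
    frames so the downstream two-frame moving average barely attenuates the
    peak. Returns the trace and a ground-truth dict with the true amplitude,
    baseline and peak frames.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    width = duty * period_frames
    if width < 10:
        raise ValueError("pulse width duty*period must be >= 10 frames")
    n_frames = n_beats * period_frames + period_frames // 2
    w = beat_waveform(n_frames, period_frames, duty)
    rng = np.random.default_rng(seed)
    trace = baseline + amplitude * w + rng.normal(0.0, noise_sd, n_frames)
    peak_frames = [k * period_frames + period_frames // 2 for k in range(n_beats)]
    truth = {"amplitude": amplitude, "baseline": baseline, "peak_frames": peak_frames}
    return trace, truth


# ---------------------------------------------------------------------------
# Hertz loading curve


def make_hertz_curve(
    E_true_kPa: float,
    R_um: float = 27.5,
    nu: float = 0.5,
    depths_um: np.ndarray | None = None,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spherical-indenter loading curve with known Young's modulus.

    Force follows ``F = (4/3) (E / (1 - nu^2)) sqrt(R) delta^{3/2}`` with
    optional multiplicative Gaussian noise, as columns
    ``indentation_um, force_uN``.
    """
    if E_true_kPa <= 0:
        raise ValueError("E_true must be positive")
    if depths_um is None:
        depths_um = np.linspace(0.0, 4.0, 81)
    depths_um = np.asarray(depths_um, dtype=float)
    if (depths_um < 0).any():
        raise ValueError("indentation depths must be nonnegative")
    force = hertz_force(depths_um, E_true_kPa, R_um, nu)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        force = force * (1.0 + rng.normal(0.0, noise_fraction, force.shape))
    return pd.DataFrame({"indentation_um": depths_um, "force_uN": force})
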