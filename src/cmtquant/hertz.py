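"""Hertz contact model fitting for nanoindentation of soft tissue.

A spherical probe of radius R pressed a depth delta into an elastic
half-space of Young's modulus E (Poisson ratio nu) carries the load

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

The model is linear in E, so the least-squares estimate over a loading
curve has the closed form

    E = (1 - nu^2) * sum(F_i * delta_i^(3/2)) / ((4/3) * sqrt(R) * sum(delta_i^3))

Units here are the instrument's native ones: depth and radius in um, force
in uN, modulus in kPa (1 kPa * um^2 = 1e-3 uN).
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: kPa * um^2 expressed in uN.
_KPA_UM2_TO_UN = 1e-3

#: Probe radius for the 55-um-diameter indenter bead, um.
DEFAULT_PROBE_RADIUS_UM = 27.5

#: Incompressible-material Poisson ratio assumed for hydrated tissue.
DEFAULT_POISSON_RATIO = 0.5


def hertz_force(
    delta_um: np.ndarray | float,
    E_kPa: float,
    R_um: float = DEFAULT_PROBE_RADIUS_UM,
    nu: float = DEFAULT_POISSON_RATIO,
) -> np.ndarray:
    """Hertz load (uN) at indentation depth delta (um)."""
    delta = np.asarray(delta_um, dtype=float)
    return (
        (4.0 / 3.0)
        * (E_kPa / (1.0 - nu**2))
        * np.sqrt(R_um)
        * delta**1.5
        * _KPA_UM2_TO_UN
    )


@dataclasses.dataclass(frozen=True)
class IndentationCurve:
    """Loading segment of one indentation: depth (um) vs force (uN)."""

    indentation_um: np.ndarray
    force_uN: np.ndarray
    probe_radius_um: float = DEFAULT_PROBE_RADIUS_UM
    poisson_ratio: float = DEFAULT_POISSON_RATIO

    def __post_init__(self) -> None:
        object.__setattr__(self, "indentation_um", np.asarray(self.indentation_um, dtype=float))
        object.__setattr__(self, "force_uN", np.asarray(self.force_uN, dtype=float))
        if self.indentation_um.shape != self.force_uN.shape:
            raise ValueError("depth and force arrays must have equal length")
        if self.probe_radius_um <= 0:
            raise ValueError("probe radius must be positive")
        if not (0 <= self.poisson_ratio < 1):
            raise ValueError("Poisson ratio must lie in [0, 1)")
        if (self.indentation_um < 0).any():
            raise ValueError("indentation depths must be nonnegative on the loading segment")


@dataclasses.dataclass(frozen=True)
class ModulusEstimate:
    E_kPa: float
    residual_rms_uN: float
    n_points: int


def _closed_form_E(delta: np.ndarray, force: np.ndarray, R: float, nu: float) -> float:
    d32 = delta**1.5
    denom = (4.0 / 3.0) * np.sqrt(R) * np.sum(delta**3) * _KPA_UM2_TO_UN
    return float((1.0 - nu**2) * np.sum(force * d32) / denom)


def hertz_fit(curve: IndentationCurve, contact_offset_search_um: float = 0.0) -> ModulusEstimate:
    """Least-squares Hertz fit of Young's modulus to a loading curve.

    The contact point is taken as pre-identified (delta = 0 at contact), as
    exported by the instrument. If ``contact_offset_search_um`` > 0, a shared
    depth offset in ``[-s, +s]`` is additionally fit by 1-D grid search,
    minimising the residual RMS.

    Requires at least 5 points with delta > 0.
    """
    delta = curve.indentation_um
    force = curve.force_uN
    if np.count_nonzero(delta > 0) < 5:
        raise ValueError("need at least 5 loading points with positive indentation")
    neg = force[delta > 0]
    if neg.size and neg.min() < -3.0 * np.abs(force).max() * 0.1:
        raise ValueError("strongly negative forces on the loading segment")

    def fit_at(offset: float) -> tuple[float, float]:
        d = delta + offset
        keep = d > 0
        if keep.sum() < 5:
            return np.nan, np.inf
        E = _closed_form_E(d[keep], force[keep], curve.probe_radius_um, curve.poisson_ratio)
        resid = force[keep] - hertz_force(d[keep], E, curve.probe_radius_um, curve.poisson_ratio)
        return E, float(np.sqrt(np.mean(resid**2)))

    if contact_offset_search_um > 0:
        offsets = np.linspace(-contact_offset_search_um, contact_offset_search_um, 81)
        fits = [fit_at(o) for o in offsets]
        E, rms = min(fits, key=lambda f: f[1])
    else:
        E, rms = fit_at(0.0)
    if not np.isfinite(E) or E <= 0:
        raise ValueError("Hertz fit failed: nonpositive or undefined modulus")
    return ModulusEstimate(E_kPa=E, residual_rms_uN=rms, n_points=int(np.count_nonzero(delta > 0)))


def sample_modulus(estimates: list[ModulusEstimate] | list[float], min_count: int = 4) -> dict:
    """Per-tissue mean modulus over repeated indentations.

    At least ``min_count`` indentations are expected per tissue; with fewer,
    the mean is still computed but flagged.
    """
    values = [e.E_kPa if isinstance(e, ModulusEstimate) else float(e) for e in estimates]
    if not values:
        raise ValueError("no modulus estimates supplied")
    flagged = len(values) < min_count
    return {
        "mean_E_kPa": float(np.mean(values)),
        "n_indentations": len(values),
        "below_min_count": flagged,
    }
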