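import numpy as np
import pytest

from cmtquant import ImageStack, ROISpec, centered_roi
from cmtquant import synth


@pytest.fixture
def texture_stack() -> ImageStack:
    """Static 3-frame band-pass texture video, scale 1 um/px."""
    tex = synth.band_pass_texture((120, 120), seed=11)
    return ImageStack(np.stack([tex] * 3), axes="t", pixel_scale_um_per_px=1.0)


@pytest.fixture
def center_roi_100() -> ROISpec:
    """100 x 100 um centre ROI for a 160 px image at 1 um/px."""
    return centered_roi((160, 160), (100.0, 100.0), 1.0, role="center")


def single_roi_scenario(peak_E_xx: float, seed: int = 3, **kwargs) -> tuple:
    """Deforming-video scenario with one centred ROI; returns (scenario, roi)."""
    roi = centered_roi((160, 160), (100.0, 100.0), 1.0, role="center")
    scn = synth.DeformationScenario(
        base_texture_seed=seed,
        n_frames=60,
        beat_period_frames=20,
        rois=(synth.ROIDeformation(roi=roi, peak_E_xx=peak_E_xx, **kwargs),),
    )
    return scn, roi
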