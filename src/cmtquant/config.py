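"""Global pipeline configuration.

A single flat JSON file carries the acquisition constants every stage needs:
the pixel calibration of the camera/objective pair, the video frame rate, the
measured micropillar spring constant, and the seed for anything stochastic.
Unknown keys are rejected so that typos fail loudly instead of silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

#: Measured spring constant of the PDMS micropillars, uN per um of tip
#: deflection. Multiplying a tracked cap deflection by this constant gives
#: the force the tissue exerts on that pillar.
DEFAULT_SPRING_CONSTANT_UN_PER_UM = 2.68


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Acquisition and transduction constants shared across the pipeline.

    Parameters
    ----------
    pixel_scale_um_per_px
        Physical size of one pixel in micrometres. Required: the objective
        magnification alone does not determine it, so it must be supplied
        from the microscope calibration.
    frame_rate_fps
        Video acquisition rate; contraction and calcium videos are acquired
        at 30 or 15 frames per second.
    pillar_spring_constant_uN_per_um
        Pillar stiffness used to convert deflection to force.
    rng_seed
        Seed for every stochastic step (synthetic data, noise realisations).
    """

    pixel_scale_um_per_px: float
    frame_rate_fps: float = 30.0
    pillar_spring_constant_uN_per_um: float = DEFAULT_SPRING_CONSTANT_UN_PER_UM
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_scale_um_per_px",
            "frame_rate_fps",
            "pillar_spring_constant_uN_per_um",
        ):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not isinstance(self.rng_seed, int):
            raise ValueError(f"rng_seed must be an integer, got {self.rng_seed!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = json.loads(path.read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must contain a JSON object")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; expected a subset of {sorted(known)}"
            )
        if "pixel_scale_um_per_px" not in data:
            raise ValueError("config must provide pixel_scale_um_per_px")
        return cls(**data)
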