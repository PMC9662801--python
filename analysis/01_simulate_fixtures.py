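#!/usr/bin/env python
"""Generate one synthetic fixture of every kind and record their ground truth.

Pixel data (TIFF stacks) go to scratch/sim/; the ground-truth manifest the
later analyses are scored against goes to results/fixture_manifest.csv.
"""

from pathlib import Path

import pandas as pd

from cmtquant import centered_roi, write_stack
from cmtquant import synth

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sim"
RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260926


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []

    roi = centered_roi((160, 160), (100.0, 100.0), 1.0, role="center")
    scn = synth.DeformationScenario(
        base_texture_seed=SEED, n_frames=60, beat_period_frames=20,
        rois=(synth.ROIDeformation(roi=roi, peak_E_xx=-0.014),),
    )
    stack, truth = synth.make_deforming_video(scn, 1.0)
    write_stack(stack, SCRATCH / "deforming.tif")
    truth.to_csv(SCRATCH / "deforming_truth.csv", index=False)
    rows.append({"fixture": "deforming", "ground_truth": "peak E_xx = -0.014", "frames": 60})

    twitch = synth.TwitchScenario(peak_deflection_um=1.0, n_frames=60, beat_period_frames=60, seed=SEED)
    stack, truth = synth.make_pillar_video(twitch, 2.68, 0.5)
    write_stack(stack, SCRATCH / "pillar.tif")
    truth.to_csv(SCRATCH / "pillar_truth.csv", index=False)
    rows.append({"fixture": "pillar", "ground_truth": "peak force 2.68 uN", "frames": 60})

    bars = (synth.Bar((35.0, 30.0), 0.2, 11.0), synth.Bar((90.0, 40.0), 1.1, 14.0),
            synth.Bar((50.0, 85.0), 2.2, 8.0), synth.Bar((95.0, 95.0), 0.8, 4.0))
    stack, truth = synth.make_fibril_stack(synth.FibrilScenario(bars=bars, seed=SEED))
    write_stack(stack, SCRATCH / "fibrils.tif")
    rows.append({"fixture": "fibrils", "ground_truth": f"total length {truth} um", "frames": 3})

    trace, truth_ca = synth.make_calcium_trace(100.0, 50.0, 4, 60, noise_sd=2.0, seed=SEED)
    pd.DataFrame({"frame": range(len(trace)), "intensity": trace}).to_csv(
        SCRATCH / "calcium.csv", index=False
    )
    rows.append({"fixture": "calcium", "ground_truth": "amplitude 100 a.u.", "frames": len(trace)})

    curve = synth.make_hertz_curve(1.5, noise_fraction=0.01, seed=SEED)
    curve.to_csv(SCRATCH / "hertz_curve.csv", index=False)
    rows.append({"fixture": "hertz", "ground_truth": "E = 1.5 kPa", "frames": len(curve)})

    manifest = pd.DataFrame(rows)
    manifest.to_csv(RESULTS / "fixture_manifest.csv", index=False)
    print(manifest.to_string(index=False))
    print(f"\npixel fixtures in {SCRATCH}, manifest in {RESULTS/'fixture_manifest.csv'}")


if __name__ == "__main__":
    main()
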