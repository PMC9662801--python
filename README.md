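# cmtquant

Quantification pipeline for focal laser injury in engineered cardiac
microtissues (CMTs) — 3-D constructs of iPSC-derived cardiomyocytes and
fibroblasts suspended between two flexible micropillars. After a focal
injury, the questions are mechanical and functional: how much contractile
force is lost, how does the injured region deform while its neighbours keep
beating, how do calcium transients, myofibril content, cell death, and
tissue stiffness change? `cmtquant` implements the full measurement chain
from raw microscopy to those numbers, for experimentalists analysing CMT
time-lapse videos, confocal z-stacks, and nanoindentation exports.

## What it computes

- **Regional strain** (`cmtquant.strain`). Shi-Tomasi corners in each ROI
  are tracked with an iterative pyramidal Lucas-Kanade scheme; the per-ROI
  average deformation gradient **F** is fit in least squares from the
  tracked displacements and converted to the Green-Lagrange tensor
  **E** = ½(FᵀF − I). Beats are partitioned from the mean absolute
  displacement trace (n peaks → n−1 temporal reference points → n−2
  periods); each period reports its signed maximum-magnitude E_xx along the
  pillar-to-pillar axis (negative in contraction, positive when an injured
  region is passively stretched), averaged over periods.
- **Twitch force and resting tension** (`cmtquant.force`). Pillar caps are
  tracked by upsampled template cross-correlation; force = k·deflection
  with the measured spring constant k = 2.68 μN/μm. Outputs: diastolic
  baseline, beat-averaged twitch (peak − baseline), day-0-normalized
  twitch, change in resting tension, time-to-peak and 50%-relaxation time.
- **Myofibril length** (`cmtquant.fibrils`). Per z-slice: |Laplacian| →
  Gaussian (σ = 2 px) → Otsu, speckle-suppressed by the Otsu mask of the
  median-filtered slice; region-properties segments strictly longer than
  6 μm (ellipse-equivalent major axis) are summed, then averaged over
  slices.
- **Calcium transients** (`cmtquant.calcium`). ROI mean intensity per
  frame, two-frame moving average, per-beat amplitude (peak minus preceding
  diastolic level), normalized to the imaging session's control-centre mean.
- **Death/fibrosis stains** (`cmtquant.stains`). Otsu masks for necrosis
  (7-AAD) and apoptosis (phosphatidylserine); the apoptosis mask is removed
  from the necrosis mask by set difference before the area ratio; DAPI
  median and vimentin/fibronectin mean intensity over projections.
- **Stiffness** (`cmtquant.hertz`). Closed-form least-squares fit of the
  Hertz contact model F = (4/3)·E/(1−ν²)·√R·δ^{3/2} (spherical probe,
  R = 27.5 μm, ν = 0.5), averaged over ≥ 4 indentations per tissue.
- **Synthetic ground truth** (`cmtquant.synth`). Every stage has a
  generator producing its input with analytic truth: textured videos
  deforming under prescribed affine maps, twitching pillar caps, blurred
  fibril bars, calcium pulse trains, Hertz curves.

## Worked example

The numbered drivers under `analysis/` run each stage on synthetic data and
write tables to `results/`. For example, regional strain recovery:

```bash
python analysis/03_regional_strain.py
```

```
 prescribed_E_xx  recovered_E_xx  abs_error  n_periods
         -0.0550        -0.05497   0.000030          1
         -0.0280        -0.02814   0.000140          1
         -0.0140        -0.01401   0.000010          1
          0.0060         0.00601   0.000009          1
...
injured-tissue scenario (systolic bulging of the centre):
     roi  prescribed_E_xx  recovered_E_xx
  center            0.006         0.00599
adjacent           -0.028        -0.02809
```

Each row is one synthetic beat video: the prescribed peak E_xx (e.g. −2.8%
contraction) versus what the tracking pipeline recovers — agreement to a few
parts in 10⁵. The injured-tissue scenario shows the characteristic
signature of a focal injury: the centre is stretched (+0.6%) while the
adjacent region keeps contracting (−2.8%). Similarly,
`analysis/04_twitch_force.py` prints a twitch of 2.680 μN for a 1.0 μm peak
cap deflection, a normalized post-injury twitch of 0.61, and a −80 μN
change in resting tension.

The same pipeline runs on real data through the CLI
(`cmtquant strain|force|calcium|segment-fibrils|stains|hertz|simulate`),
with a JSON config carrying the pixel calibration, frame rate (30 or
15 fps) and spring constant.

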