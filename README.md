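# srbeam3d

Adaptive weight-based 3D beamforming and super-resolution ultrasound
localization microscopy (ULM) for matrix-array plane-wave imaging.

## The problem

3D ultrasound with a matrix array (here a 32 x 32, 7.8 MHz probe with a
9.6 mm x 10.2 mm aperture) and single-plane-wave transmit suffers from a
wide main lobe and strong side lobes: bright microbubbles cast side lobes
that can be mistaken for bubbles, and overlapping main lobes prevent the
isolation of close bubbles.  Both effects lengthen super-resolution
acquisitions.  This package implements and compares per-voxel *adaptive
weight-based* beamformers that sharpen the point-spread function at almost
delay-and-sum cost, together with everything needed to evaluate them in
silico: a point-scatterer channel-data simulator, PSF metrics, and the
bubble localization pipeline.

## The beamformers

For delayed analytic channel signals `s_n(t)` with element sensitivities
`a_n(t) = sinc(Lu/λ) sinc(Lv/λ) cosθ` (channels with `a_n < 0.5` are
dropped; `N` counts the survivors):

- **DAS** — apodized coherent sum `y = Σ a_n s_n`.
- **p-DAS** — `ŷ = Σ (s_n/|s_n|) |s_n|^{1/p}` then `y = (ŷ/|ŷ|)|ŷ|^p`
  (p = 4), reconstructed on a 0.01 mm depth grid and band-pass filtered
  along depth around the fundamental axial frequency `2 f0 / c` to remove
  the harmonics created by the nonlinearity.
- **CF** — coherence factor `W_CF = |Σ s_n|² / (N Σ |s_n|²)`, applied as
  `y_CF = W_CF · y`.
- **CV / CV_N** — coherence-to-variance weight
  `W_V = |Σ s_n|² / Σ |x_n − mean(x)|²` with `x_n = s_n / a_n`
  (inverse-apodized; `x_n = s_n` for the plain variant CV_N), applied as
  `y_CV = W_V · y`.  The variance denominator collapses at the centre of
  the PSF and grows quickly off-peak, giving the sharpest main lobe of the
  four.

## Worked example

```python
import numpy as np
from srbeam3d import (NoiseSpec, VoxelGrid, add_noise, beamform_multi,
                      make_probe, scenario, simulate_channels)
from srbeam3d.forward_model import required_duration
from srbeam3d.psf_metrics import psmr

probe = make_probe()                       # 32x32, 7.8 MHz, 9.6x10.2 mm
scene = scenario("five_axial")             # five scatterers, 15..25 mm deep
frame = simulate_channels(probe, scene,
                          duration=required_duration(probe, 27.0, 2.0))
frame = add_noise(frame, NoiseSpec(channel_snr_db=10.0, rng_seed=1))

grid = VoxelGrid.from_bounds(((-2, 2), (-2, 2), (13, 27)), 0.05)
vols = beamform_multi(frame, probe, grid, ["das", "cv"])
for name, vol in vols.items():
    report = psmr(vol, scene.positions)
    print(name,
          "lateral FWHM %.3f mm" % np.nanmean(report.fwhm_lateral),
          "max-PSMR %.1f dB" % report.max_psmr)
```

prints (exact values depend on the noise seed):

```
das lateral FWHM 0.558 mm max-PSMR 0.9 dB
cv  lateral FWHM 0.177 mm max-PSMR -10.7 dB
```

i.e. the CV weighting narrows the lateral main lobe about 3-fold and
pushes every side lobe below the weakest scatterer's main lobe (negative
max-PSMR), while plain DAS leaves a strong-scatterer side lobe *above*
the weakest main lobe (positive max-PSMR) — the failure mode that creates
false bubbles in ULM.

The same comparison is available from the shell:

```bash
srbeam3d reproduce-tables --snr-db 10 --seed 1 --out-dir out/
srbeam3d simulate --scenario five_axial --snr-db 0 --seed 1 --out frame.h5
srbeam3d beamform --in frame.h5 --method cv --out vol.nii.gz
srbeam3d ulm --stack stack.h5 --method cv --ncc-th 0.3 --bg-db -40 --out density.nii.gz
```

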