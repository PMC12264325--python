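# detrack

Markerless lung-tumor motion monitoring with a room-mounted stereoscopic
kV imaging system, simulated end to end: dual-energy (DE) bone
suppression, DRR template matching, stereoscopic triangulation, and
monoscopic 3D estimation with a Gaussian motion PDF for the periods when
the rotating linac gantry blocks one imaging view.

Lung tumors move ~2 cm with breathing during stereotactic body
radiotherapy. A stereoscopic kV imager can localize the tumor in 3D
without implanted markers, but two problems get in the way: overlying
bone (ribs in one view, the spine in the other) confuses template
matching, and during an arc delivery the gantry periodically blocks one
of the two views. The package implements the imaging chain that addresses
both — DE log subtraction to cancel bone, and a motion-prior estimator
for single-view frames — together with a synthetic digital thorax,
breathing trajectories, and an x-ray projection simulator, so the whole
chain runs and is tested without any measured data. It is aimed at
medical-physics researchers prototyping markerless tracking pipelines.

## The method

Per frame and view, a soft-tissue image is formed by weighted log
subtraction of the low-energy from the high-energy acquisition,

    log I_DEST = log I_HE − w_s · log I_LE,
    log I_DEB  = −log I_HE + w_b · log I_LE,

with `w_s` chosen per frame by minimizing the bone contrast-to-noise
ratio between a bone ROI and a matched soft-tissue ROI (bone vanishes at
`w_s* = μ_bone(HE)/μ_bone(LE)` for Beer–Lambert projections). Quantum
noise is reduced by adding the high-pass-filtered bone image
(anti-correlated noise reduction, `w_n = 0.9`, cutoff 0.2 cycles/pixel).
The tumor is located in each 2D view as the global maximum of the
normalized cross-correlation

    NCC(u,v) = Σ (I − Ī_{u,v})(t − t̄) / (N σ_I σ_t)

between the image and a tumor-only DRR template. With both views
available the two back-projected rays are triangulated
(common-perpendicular midpoint); with one view blocked, the 3D position
is the point on the measurement ray `x(t) = p + t·d` maximizing a
Gaussian motion PDF N(μ, Σ) fitted online from the stereoscopic
estimates:

    t* = dᵀΣ⁻¹(μ − p) / (dᵀΣ⁻¹d).

A frame counts as a success when the 3D error is below 3 mm.

## Worked example

Track a 2.6 cm, 140 HU tumor through a 100-frame, 1.67 Hz series over a
full gantry arc, with both techniques:

```python
import numpy as np
from detrack.evaluation import (SweepConfig, _Bench, _prepare_tumor,
                                run_condition, success_rate_by_region,
                                accuracy_precision)
from detrack.localization import gantry_schedule

cfg = SweepConfig()                      # 128x128 detector sampling
bench = _Bench.build(cfg)                # thorax + geometry + static DRRs
tumor, templates, ref = _prepare_tumor(bench, 26.0, (140.0, 35.0))
schedule = gantry_schedule(n_frames=cfg.n_frames)
for technique in ("DE", "SE"):
    records = run_condition(bench, tumor, templates, ref, technique,
                            1.0, schedule, traj_seed=1, noise_seed=2)
    rates = success_rate_by_region(records)
    acc, prec = accuracy_precision(records)
    print(f"{technique}: success", {k: round(v, 3) for k, v in rates.items()})
    print("   accuracy (LR,AP,SI) mm:", np.round(acc, 2),
          " precision:", np.round(prec, 2))
```

prints

```
DE: success {'STEREO': 1.0, 'MONO_A': 1.0, 'MONO_B': 1.0, 'ALL': 1.0}
   accuracy (LR,AP,SI) mm: [ 0.17 -0.32  0.  ]  precision: [0.22 0.33 0.41]
SE: success {'STEREO': 1.0, 'MONO_A': 0.966, 'MONO_B': 0.931, 'ALL': 0.97}
   accuracy (LR,AP,SI) mm: [-0.65 -1.4  -0.68]  precision: [0.35 0.59 0.67]
```

Both techniques localize this large tumor within ~1 mm on average; the
single-energy (SE) technique already loses frames in the spine-obstructed
monoscopic-B region, and the gap widens sharply for smaller or
lower-density tumors, where DE stays near-perfect — run
`detrack sweep --seed 0 --outdir out` for the full size/density/mAs
matrix as CSV/JSON reports.

The same pipeline is available from the shell: `detrack simulate`
(phantom + series → TIFF/CSV), `detrack track` (series → per-frame
localization records CSV), `detrack evaluate` (records → summary), and
`detrack sweep` (experiment matrix), each accepting a YAML config,
`--seed` and `--outdir`.

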