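# gliomalatt

Anatomy-aware lattice simulation of glioblastoma xenograft growth in the
mouse brain, with likelihood-free (ABC) parameter estimation from histology
slices and in-silico drug-combination experiments.

Glioblastoma cells invade preferentially along white-matter tracts and
blood vessels, producing strongly anisotropic tumors. This package is for
modelers and experimentalists who want to (i) simulate that growth on a 3D
anatomical scaffold, (ii) fit the growth/invasion parameters of a specific
tumor from a single segmented histology section, and (iii) probe how the
fitted tumor would respond to hypothetical anti-migration/anti-proliferation
drug mixes.

## Model

Cells occupy a cubic lattice (43 µm voxels by default) with carrying
capacity *K* = 3 cells per voxel. At each time step, every cell alive at
the step start acts once, in random order: it proliferates with probability
*p<sub>p</sub>* (offspring share its voxel, act from the next step, and are
only produced below capacity), then attempts a move with probability
*p<sub>m</sub>* to one of the six face neighbors. The move direction is
drawn from

&nbsp;&nbsp;&nbsp;&nbsp;**P** = (1/6)(1 − w<sub>wm</sub> − w<sub>bv</sub>) **1** + w<sub>wm</sub> **P**<sub>wm</sub> + w<sub>bv</sub> **P**<sub>bv</sub>,

where **P**<sub>wm</sub> (and analogously **P**<sub>bv</sub>) sums the unit
vectors toward every white-matter voxel within sensing radius *d* = 5,
folded onto the six lattice axes and L1-normalized. Moves into full voxels
or out of the brain are aborted. Tumors are seeded as a radius-8 sphere at
3 cells/voxel (6327 cells).

Fitting uses rejection ABC: parameter sets are drawn from uniform priors
(p<sub>m</sub> ∼ U(0,1), p<sub>p</sub> ∼ U(0,0.015), w<sub>wm</sub>,
w<sub>bv</sub> ∼ U(0,1) with w<sub>wm</sub> + w<sub>bv</sub> ≤ 1), one
simulation is run per set, and the sets whose 8-component geometric summary
vector — component count, area and eccentricity moments, perimeter
extremes, max filled area — lies closest to the observed slice's are
retained. Retained samples are sharpened by Epanechnikov-weighted
local-linear regression on the summary discrepancies (logit-transformed so
samples stay inside the priors), and point estimates are means of a bounded
Epanechnikov KDE (bandwidth 1/10).

## Worked example

Simulate a tumor on a synthetic brain phantom, then recover its parameters
from one virtual histology slice:

```python
import numpy as np
from gliomalatt import (
    default_atlas, SimulationParams, run_simulation, extract_slice,
    ExperimentConfig, SimulationProtocol, fit_abc, rescale_parameters,
)

atlas = default_atlas((64, 64, 64), seed=0)

truth = SimulationParams(p_m=0.8, p_p=0.004, w_wm=0.35, w_bv=0.25, T=200, seed=11)
observed = run_simulation(truth, atlas, {"radius": 6})
obs_slice = extract_slice(observed.state, axis=2, index=32)

config = ExperimentConfig(n_sims=1000, accept_frac=0.05,
                          protocol=SimulationProtocol(T=200, init_radius=6), seed=1)
result = fit_abc(obs_slice, atlas, config)
for name, (est, q10, q90) in result.point_estimates.items():
    print(f"  {name:5s} = {est:.4f}  (10%: {q10:.4f}, 90%: {q90:.4f})")
```

prints (a few minutes on one CPU):

```
  p_m   = 0.8317  (10%: 0.6266, 90%: 0.9697)
  p_p   = 0.0049  (10%: 0.0020, 90%: 0.0082)
  w_wm  = 0.4668  (10%: 0.2004, 90%: 0.6872)
  w_bv  = 0.2461  (10%: 0.1299, 90%: 0.3863)
```

The point estimates bracket the ground truth (0.8, 0.004, 0.35, 0.25): the
migration and proliferation probabilities and the vessel attraction are
recovered closely, the white-matter attraction with a wider credible band.
The acceptance threshold `result.delta` (here 1.62) is an inverse measure
of fit quality — the largest summary distance among accepted sets.
`rescale_parameters(p_m, p_p, spacing_um, duration_days, steps)` converts
the per-step probabilities to a migration rate in µm/h and a proliferation
rate in 1/day for a given experiment duration.

The same machinery is exposed as a CLI:

```bash
gliomalatt synthesize-anatomy --shape 64,64,64 --seed 0 --out atlas/
gliomalatt simulate --atlas atlas/ --params params.yaml --steps 1800 --out run.npz
gliomalatt fit --observed slice.png --atlas atlas/ --nsims 1000 --out fitdir/
gliomalatt model-compare --observed slice.png --atlas atlas/ --out support.json
gliomalatt treat --params fitted.yaml --atlas atlas/ --schedule 30,60 --out sweep.csv
gliomalatt benchmark --out benchmark.csv
```

`benchmark` runs the 16-case synthetic recovery study (every low/high
combination of the four parameters) comparing Jaccard-based ABC, geometric
ABC, and geometric ABC with regression adjustment by their mean relative
parameter error. `treat` sweeps drug mixes from pure anti-migration to pure
anti-proliferation and reports cell count and convex-hull volume relative
to an untreated control.

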