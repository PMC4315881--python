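# fidtrack

Fast 3D localization of N fiducial markers from 1D MR projections, for
real-time instrument tracking in MRI-guided interventions (e.g. a
prostate-biopsy probe carrying resonant microcoil markers).

## The method

A 1D projection acquired with a single frequency-encoding gradient shows
each marker as a peak at pₖ = **N**ₖ·**P**, the offset of the marker
position **P** along the projection direction **N**ₖ; every peak
constrains **P** to a plane. The tracking algorithm:

1. detects peaks per projection with an SNR gate and refines them to
   sub-pixel accuracy by three-point Gaussian interpolation
   X̂ = x − ½ (ln c − ln a)/(ln a + ln c − 2 ln b);
2. selects three *reference* projections — the first triple, in the
   ranking by decreasing |det(**N**₁,**N**₂,**N**₃)|, whose projections
   each show exactly N well-separated peaks — and intersects all N³
   one-peak-per-projection plane combinations,
   **P** = [p₁(**N**₂×**N**₃) + p₂(**N**₃×**N**₁) + p₃(**N**₁×**N**₂)] / det;
3. eliminates the N³ − N fictitious candidates with the remaining *test*
   projections: a candidate survives only if each test projection has a
   peak within a tolerance ε of the candidate's projected value (enlarged
   to two pixels when peaks have merged and the projection carries fewer
   than N peaks);
4. accepts the frame only when exactly N candidates survive.

Projection directions are the 3/9/13 regularly distributed lines of the
6/18/26 voxel neighbourhoods. The localized markers are then matched to
the instrument's nominal marker model by their (all-distinct) pairwise
distances, a proper rigid transform is fitted by least squares, and the
needle tip follows from the known probe geometry. A spoiled-GRE signal
model of the microcoil excitation (effective flip angle α_eff = Q·α_app)
and Monte Carlo robustness/accuracy/targeting studies round out the
package. Everything runs on synthetic data generated by the package
itself — no scanner required.

## Worked example

Localize three markers from 13 noisy projections (peak noise 0.08 mm):

```python
import numpy as np
from fidtrack import (LocalizationConfig, direction_subset,
                      localize, project_markers)

markers = np.array([[40.0, -55.0, 25.0],
                    [-70.0, 30.0, -45.0],
                    [15.0, 80.0, 60.0]])
dirs = direction_subset(13)
rng = np.random.default_rng(0)
peaksets = project_markers(markers, dirs, 0.08, rng)

res = localize(peaksets, LocalizationConfig(n_markers=3, epsilon=0.8))
print(res.success, res.reference_triple.indices, res.n_candidates_initial)
print(res.points.round(3))
```

prints

```
True (0, 1, 2) 27
[[-69.924  29.957 -45.011]
 [ 14.944  80.029  60.051]
 [ 40.104 -54.992  25.01 ]]
```

The reference triple (0, 1, 2) is the coordinate axes (|det| = 1, the
best-conditioned choice); 27 candidates were generated and the first test
projection already removed the 24 fictitious ones. The recovered points
match the true markers to better than 0.11 mm — a few peak-noise standard
deviations spread over three planes.

The same pipeline is available from the shell:

```sh
fidtrack directions --level 26 --out dirs.txt
fidtrack localize --peaks peaks.csv --n-markers 3 --epsilon 0.8
fidtrack simulate-robustness --sigma 0.08 --trials 10000 --seed 1 --out table.csv
fidtrack simulate-targeting --trials 3000 --seed 7 --out targeting.csv
fidtrack signal-series --alpha-app 0.2 --q 120 --n 13
```

`signal-series` shows why the tracking sequence uses a small applied flip
angle: with Q = 120 the echoes of a 13-projection set start at 0.317 and
decay (0.290, 0.267, ...) toward the spoiled steady state; larger flip
angles start brighter but decay much faster, and the worst echo of the
set is maximized near α_app = 0.2–0.3°.

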