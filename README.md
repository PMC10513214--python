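# sbrd — confinement-corrected diffusion mapping in bacteria

Diffusion coefficients measured inside bacteria by single-molecule
displacement mapping (SMdM) are systematically underestimated: within the
1.5 ms stroboscopic lag a molecule bounces off the cell wall, and the camera
sees only the 2D projection of its 3D walk. The bias grows with D and is
strongest at the cell poles, which confounds the biological question of
whether diffusion at the poles is genuinely slower than at the cell center.

This package implements the full analysis chain for rod-shaped cells
(*E. coli*-like spherocylinders):

- **Detection** — cells are fitted as *billiards* (2D stadium outlines) by
  maximum likelihood over the localization cloud, with the per-point density
  `p_i = (h_i/V + 1/N)/2` (thickness-weighted signal vs uniform noise),
  automatic splitting of over-long fits into dividing pairs with a shared
  septum, and new/old pole labelling.
- **SMdM** — peak pairing within 600 nm across stroboscopic frame couples,
  per-pixel (100 nm) and per-region maximum-likelihood fits of the
  displacement PDF `p(r,t) ∝ (2r/4Dt)·e^{−r²/4Dt} + k·r`, truncated and
  normalized on [0, r_max], with a linear background term `k` for pairing
  ambiguity; the diffusion-vs-complex-mass power law `D = αM^β`.
- **SbRD (simulation-based reconstructed diffusion)** — the correction: the
  measured starts are re-embedded in 3D (z uniform over the local chord),
  forward Brownian simulations with exact specular reflection are run at a
  candidate D, and the candidate whose simulated apparent coefficient
  matches the measured one is the corrected value `D_cc`; 10 repeats with
  fresh z-assignments and noise are averaged.
- **Synthetic data** — a generator that emits localization tables with known
  ground truth (homogeneous cells, slow-pole regions, dividing pairs), so
  every stage is testable without any external data.
- **Statistics** — Shapiro-Wilk, Mann-Whitney U, one-sided Wilcoxon
  signed-rank on per-cell pole residuals, ratio summaries and KDE figures.

The fit-shaped stages are sklearn-style estimators (`BilliardDetector`,
`DisplacementDiffusionMLE`, `PowerLawMassScaling`, `ConfinementCorrector`)
with `fit`/`predict` and trailing-underscore attributes; module-level
functions wrap them.

## Worked example

Simulate a homogeneous cell, measure the apparent coefficient, correct it:

```python
import numpy as np
from sbrd import Billiard, Spherocylinder
from sbrd.simulate import SimulationConfig, simulate_smdm_displacements
from sbrd.geometry import RegionLabel
from sbrd.sbrd import SbRDConfig, correct_region

shape = Spherocylinder(Billiard.from_center((0, 0), 2.25, 0.45, 0.0))
cfg = SimulationConfig(D_input=10.0, n_particles=100, shape=shape,
                       total_time=1.0, seed=1)
disp = simulate_smdm_displacements(cfg)          # ~66k displacements

poles = (RegionLabel.POLE_LEFT, RegionLabel.POLE_RIGHT)
d_cc, d_app = correct_region(shape, disp, poles,
                             SbRDConfig(n_repeats=10, seed=2),
                             background=False, frame_coords=True)
print(f"apparent {d_app:.2f}, corrected {d_cc:.2f} um^2/s")
```

```
apparent 7.69, corrected 9.79 um^2/s
```

The pole region of a 2.25 × 0.9 μm cell at a true D of 10 μm²/s reads only
~7.7 μm²/s through SMdM — a 23% confinement bias — and the recursive
simulation matching recovers the input value within sampling error.

The same flow runs from the shell:

```sh
sbrd synth scene.yaml scene/           # synthetic localizations + truth
sbrd detect --localizations scene/localizations.csv --out cells.json
sbrd smdm --cells cells.json --localizations scene/localizations.csv --out maps.h5
sbrd correct --maps maps.h5 --cells cells.json --out sbrd.h5
sbrd report --regions run/regions.csv --out report/
```

or end-to-end via `sbrd run config.yaml` / `sbrd.pipeline.run_pipeline`.

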