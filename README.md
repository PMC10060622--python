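# spinedvc

Zero-strain digital volume correlation (DVC) uncertainty analysis for
vertebral microCT, with a synthetic trabecular phantom generator.

## The problem

DVC measures 3D displacement and strain fields inside bone by elastically
registering volumetric images of a specimen in two states. Before trusting
DVC strains under load, the measurement uncertainty must be quantified with
a **zero-strain test**: the specimen is scanned twice without loading (with
repositioning between scans), the pair is registered, and — since the true
displacement variation and strain are zero — everything the pipeline reports
is measurement error. This matters particularly for metastatic vertebrae,
whose lytic (resorbed) and blastic (dense, low-texture) lesions make the
trabecular microstructure highly heterogeneous.

`spinedvc` implements the full zero-strain pipeline for researchers running
such precision studies:

- **synthetic phantoms** (`spinedvc.synth`) — seeded vertebral-body
  surrogates with controllable bone volume fraction, trabecular thickness,
  cortical shell, lytic/blastic lesions, marrow, air bubbles, scanner noise,
  and exactly known ground truth (masks, motions, analytic affine fields);
- **preprocessing** (`spinedvc.preprocess`) — air-bubble removal, 3D median
  denoising, Otsu+5% bone segmentation, body-mask construction, rigid
  alignment of repeated scans, merged masks and the eroded evaluation VOI;
- **the DVC engine** (`spinedvc.registration`) — global elastic registration
  on a regular grid of cubic cells with side NS voxels (the nodal spacing),
  solving the linearized intensity-conservation residual
  `r(x) = f(x) − g(x + u(x)) − s(x)·h(x)` by smoothed least squares in a
  trilinear nodal basis, iterated with rewarping;
- **strain differentiation** (`spinedvc.strain`) — voxel detection (cells
  without a node in the VOI are dropped), then trilinear shape-function
  differentiation to the six small-strain components per node;
- **morphometry** (`spinedvc.morphometry`) — BV/TV, St.Th., St.Sp. (3D
  sphere-fitting local thickness of structure and background) and
  St.N = (BV/TV)/St.Th;
- **uncertainty metrics** (`spinedvc.uncertainty`) — per-axis random
  displacement error, per-component systematic/random strain error, and

      m_k  = (1/6) Σ_c |ε_c,k|
      MAER = (1/N) Σ_k m_k                       (accuracy)
      SDER = sqrt((1/N) Σ_k (m_k − MAER)²)       (precision)

  over the N retained grid nodes, plus the 27-subROI partition
  (3 longitudinal levels × 9 sectors, 1%-of-body exclusion rule),
  Mann–Whitney / Kruskal–Wallis comparisons and OLS correlations;
- **orchestration** (`spinedvc.pipeline`, CLI `spinedvc`) — the whole study
  over many specimens and an NS sweep, with VTK/CSV export and
  deterministic seeding.

A bundled reference dataset (`spinedvc.tables`) carries published
per-vertebra morphometry of 15 metastatic and 9 control human vertebral
bodies (microCT, 39 μm) so the group statistics can be reproduced without
the original scans.

## Worked example

```python
import numpy as np
from spinedvc import (PhantomSpec, generate_phantom, simulate_repeat_scan,
                      RegistrationSettings, register_elastic, make_voi_dvc,
                      extract_mesh, compute_nodal_strains, error_report)

spec = PhantomSpec(shape=(160, 160, 160), target_bvtv=0.15, noise_sd=0.0, seed=7)
vol, truth = generate_phantom(spec)                       # Scan basis
scan1 = simulate_repeat_scan(vol, truth, None, noise_sd=8.0, seed=100)
scan2 = simulate_repeat_scan(vol, truth, None, noise_sd=8.0, seed=200)

field = register_elastic(scan1, scan2, truth.body_mask,
                         RegistrationSettings(ns=16))
_, voi = make_voi_dvc(truth.body_mask, truth.body_mask, margin=25)
mesh = extract_mesh(field.grid, voi)
strain = compute_nodal_strains(mesh, field)
rep = error_report(field, mesh, strain)
print(np.round(rep.disp_random_um, 2), round(rep.maer_ue), round(rep.sder_ue))
```

This prints

```
[1.14 1.15 1.21] 1738 739
```

— the random displacement error is ~1.2 μm per axis (far below the 39 μm
voxel size), and the strain accuracy/precision of this zero-strain pair at
NS = 16 voxels is MAER ≈ 1738 με, SDER ≈ 739 με. Repeating at NS = 8 and
NS = 32 gives SDER ≈ 3556 and ≈ 168 με: precision improves as the
measurement spatial resolution coarsens, which is the fundamental
trade-off the NS sweep quantifies.

A study over many phantoms runs from the shell:

```sh
spinedvc zero-strain-study --config study.yaml --out results/ --seed 1
spinedvc report --study-dir results/
```

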