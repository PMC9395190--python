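# dipolecycle

Analysis of 3D single-cell migration driven by two phase-shifted
oscillating force dipoles.

Mesenchymal cells moving through soft fibrous matrices often lack the
coherent front-to-back actin flow that polarizes fast 2D migration.
Instead they run two acto-myosin contraction units, one on each side of
the nucleus, that periodically pinch the surrounding matrix. Because
motion at cell scale is inertialess, a reciprocal sequence of shape
changes produces no net displacement (Purcell's scallop theorem):
directed migration requires the two pinching cycles to run **out of
phase**. This package implements the full quantitative chain that tests
this mechanism on matrix-deformation data, together with the minimal
bead models that anchor its interpretation. It is written for
biophysicists analyzing time-lapse recordings of cells in cell-derived
matrices, and for modelers studying crawling at zero Reynolds number.

## What it computes

Given a time-lapse image stack (or a pre-computed displacement-rate
field `u_i(n)` in µm/min):

1. **tracker** — sparse matrix-deformation fields by pyramidal
   Kanade–Lucas–Tomasi feature tracking with median drift subtraction.
2. **oscillation** — divergence kymographs projected on the cell axis;
   front/back traces; periods from the first significant peak of the
   coefficient-normalized autocorrelation; front–back lag from the
   extremal cross-correlation peak; phase shift ψ = 2π·lag/T.
3. **multipole** — force-moment readouts of the deformation rate, with
   Δ(n) the sample position relative to the cell center:

       S_ij  = Σ_n sym(Δ_i u_j)        (dipole, µm²/min)
       Q_ijk = Σ_n Δ_i Δ_j u_k         (quadrupole, µm³/min)

   The main dipole D (largest-magnitude eigenvalue of S, sign kept) and
   main quadrupole Q (contraction of Q_ijk along the cell axis) trace a
   trajectory in the D–Q plane; its per-cycle shoelace area (µm⁵/min²,
   also normalized to the bounding rectangle) is finite exactly when
   time-reversal symmetry is broken — the signature of migration.
4. **bead_model** — a four-bead cell with two oscillating dipolar units
   (amplitude d, period T, phase shift ψ) simulated as a low-Reynolds
   swimmer (Oseen coupling, force-free) and as a matrix-adhering crawler
   (slip-bond adhesion, elastic substrate coupling), reproducing the
   scallop theorem, V ∝ d²/T for the swimmer, and V ∝ 1/T² for the
   crawler.
5. **synthetic_data / pipeline** — seeded generators for every input the
   stages consume (pinch fields, warped fiber textures, traces) and an
   end-to-end runner with migrating / non-migrating classification and
   the reported statistics (Pearson, Kruskal–Wallis, log–log slope fits).

## Worked example

Analyze a synthetic cell whose back pinch lags its front pinch by a
quarter period (ψ = π/2, T = 8 min, 2.5 µm pinch amplitude, tracker-like
noise):

```python
import numpy as np
from dipolecycle import pipeline, synthetic

params = synthetic.DipoleFieldParams(phase_shift=np.pi / 2, noise_sd=0.05, seed=11)
summary = pipeline.run(pipeline.RunConfig(field_params=params, seed=11))
for k, v in summary.to_dict().items():
    print(f"{k:>16}: {v}")
```

prints

```
    front_period: 8.0
     back_period: 8.0
             lag: 2.0
             psi: 1.5707963267948966
   absolute_area: 512631.2939378797
 normalized_area: 26.49503424994864
     area_spread: 0.0
  classification: migrating
     config_hash: fbf2b757783c
```

Both pinches oscillate with the imposed 8-min period; the front leads
the back by 2 min, i.e. ψ = 2π·2/8 = π/2, exactly the imposed shift; the
D–Q trajectory encloses 26% of its bounding rectangle — far above the
noise floor — so the cell is classified migrating. Rerunning with
`phase_shift=0.0` gives lag 0, a near-degenerate D–Q line, and
`non-migrating`.

The same stages are exposed on the command line:

```sh
dipolecycle track --in stack.tif --pixel-size 0.32 --dt 0.5 --out field.tsv
dipolecycle periods --field field.tsv --geometry geom.tsv --front 7.5 --back -7.5
dipolecycle simulate --mode crawler --T 8 --d 0.5 --psi 1.5708 --out traj.tsv
dipolecycle run --synthetic-psi 1.5708 --seed 11 --out results/
```

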