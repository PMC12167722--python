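# texkin — texture-tensor kinematics for epithelial tissue

Epithelial monolayers deform through four kinds of cellular events: cells
change shape, exchange neighbors (T1 rearrangements), divide, and die
(T2 extrusion / apoptosis). `texkin` measures all of these from segmented
cell-contour movies within one tensorial framework and checks that the
measurements obey the kinematic equations of the corresponding continuum
model. It is aimed at quantitative biologists and biophysicists analyzing
time-lapse movies of confluent 2D tissue (label images or tabulated cell
geometries), and at modelers who need a validated strain-decomposition
pipeline with ground-truth test data.

## The framework

Cell shape is coarse-grained by the **texture tensor** built from
half-links l_ik = x_k − x_i between neighboring cell centers in a region of
interest P:

    M̂⁽¹⁾ = (1/N_h) Σ_{i∈P} ½ Σ_k ω_ik · l_ik ⊗ l_ik

with ω_ik = 1 for edge contacts, ½ for fourfold-vertex contacts, N_h the
number of half-links, and outermost cells excluded. Its eigenstructure is
the coarse-grained cell ellipse: area A = π|M̂|^½, density ρ̂ = 1/A.

Between consecutive frames the tissue strain rate is estimated from the
affine transport F̂ of conserved half-links, Ĝ = (F̂ᵀF̂ − I)/(2Δt), and
decomposed by classifying appearing/disappearing half-links into events:

    Ĝ = Ŝ + R̂ + D̂ + Â,        D̂_T = R̂ + D̂ + Â,

(shape change, rearrangement, division, apoptosis). The package validates
the parameter-free kinematic equations of the continuum model on the
measured series:

    dM/dt = (∇v − D_T) M + M (∇v − D_T)ᵀ
    ∂ρ/∂t + ∇·(ρv) = (Tr D_T) ρ,     Tr R = 0,  Tr D ≥ 0,  Tr A ≤ 0.

Everything is testable without microscopy data: the built-in simulator
generates confluent polygonal tissues (hexagonal or Lloyd-relaxed Voronoi)
undergoing prescribed smooth flows plus logged T1 / division / T2 events,
with exact adjacency, lineage, velocity field and deformation gradient as
ground truth. A single-pass cross-correlation PIV and an exact
linear-assignment cell tracker connect the pipeline to raw image input.

## Worked example

Simulate a dividing tissue (250 cells, 8 one-minute intervals, ~3 divisions
per interval, weak uniform growth flow), run the full decomposition over
Lagrangian 120-px ROIs, and check the cell-number balance:

```python
import numpy as np
from texkin import analyze_scene
from texkin.synthetic import FlowSpec, SceneConfig, simulate

config = SceneConfig(
    tiling_kind="voronoi", n_cells=250, n_intervals=8, dt=1.0,
    divisions_per_interval=3,
    flow=FlowSpec(kind="affine", gradient=np.array([[0.004, 0.0],
                                                    [0.0, 0.003]])))
scene = simulate(config, seed=21)
analysis = analyze_scene(scene, tile=120.0)

table = analysis.table()   # per (ROI, interval): F, G, S, R, D, A, D_T, ρ
print(table[["roi", "interval", "G_xx", "S_xx", "D_xx",
             "n_divisions"]].head(3).to_string(index=False))

report = analysis.density_report(routes=("TrG", "truth"))
print("density-balance slope (TrG route):",
      round(report.stats["TrG"].slope, 3))
```

Output:

```
 roi  interval     G_xx     S_xx      D_xx  n_divisions
   0         0 0.004008 0.003322  0.000562            1
   0         1 0.004008 0.004008 -0.000000            0
   0         2 0.004008 0.004008 -0.000000            0
density-balance slope (TrG route): 1.017
```

Reading it: the measured tissue strain rate G_xx ≈ 0.004 min⁻¹ equals the
imposed flow gradient; in the interval containing a division, part of the
strain shifts from cell shape change (S) to the division term (D), while
event-free intervals have S = G exactly. Pooled over all ROIs the mean
traces come out Tr Ĝ ≈ 0.0070, Tr Ŝ ≈ −0.0029, Tr R̂ = 0, Tr D̂ ≈ 0.0100,
Tr Â = 0 min⁻¹ — divisions densify the tissue faster than the weak area
growth dilutes it, and cells shrink to accommodate their new neighbors. The
density-balance regression of (Δρ̂/ρ̂)/Δt + ∇·v against Tr D̂_T has slope
1.017: the cell-number equation holds on the measured series to ~2%.

The same pipeline runs from the shell:

```bash
texkin simulate --config scene.yaml --seed 1 --out scene/
texkin frames   --labels scene/labels/frame_0000.tif --out frames/
texkin validate --config scene.yaml --seed 1 --out report/
```

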