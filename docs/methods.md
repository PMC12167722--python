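# Methods

`texkin` quantifies epithelial tissue deformation from segmented
cell-contour movies and decomposes it into the contributions of the four
morphogenetic cell events — cell shape change (S), rearrangement (R),
division (D) and apoptosis (A). This note records the model, the estimators,
the numerical choices, and what the synthetic tissue generator does and does
not emulate.

## The texture tensor and its normalization

For each region of interest (ROI) P, every cell i contributes directed
half-links l_ik = x_k − x_i to its neighbors k. Links touching outermost
cells (cells bordering the image edge or the background) are excluded.
Contact weights are ω_ik = 1 for ordinary edge contacts and ω_ik = 1/2 for
cells that meet only at a fourfold (or higher) vertex. The unnormalized
texture tensor is

    M⁽⁰⁾ = Σ_{i∈P} ½ Σ_k ω_ik l_ik ⊗ l_ik          [px²]

and the half-link-normalized variant is M⁽¹⁾ = M⁽⁰⁾ / N_h, where N_h counts
the half-links in the ROI (each undirected interior pair twice; ω does not
enter N_h). M⁽¹⁾ is intensive — invariant to ROI size on homogeneous tissue
— while M⁽⁰⁾ grows with cell number; this difference is exactly what the
kinematic validation below probes. M⁽²⁾ = M⁽⁰⁾ / N_c is also provided;
further variants (M⁽³⁾, M⁽⁴⁾) are an extension point (`register_variant`)
with no default formula.

The eigen-structure of M approximates the coarse-grained cell as an ellipse:
area A = π|M|^½, density ρ = 1/A, aspect ratio √(λ₁/λ₂), orientation θ from
the major eigenvector. For a regular hexagon of center spacing d,
M⁽¹⁾ = (d²/4)·I and the texture area πd²/4 underestimates the true cell area
(√3/2)d² by the geometric factor π/(2√3) ≈ 0.907; ratios and rates are
unaffected by this constant.

Pixel-based cross-checks use per-cell second moments m̂₂c (pixel sums about
the pixel centroid, divided by pixel area) and the ROI mean
m̂₂ = (4/N_c) Σ m̂₂c. The factor 4 makes the statistic exact for ellipses: a
filled ellipse with semi-axes (r_a, r_b) has m_xx = r_a²/4. Two pixel-area
conventions are computed — contour-excluded, and including each outline
pixel split equally among its adjacent cells — the latter is unbiased
against polygon areas and is the default for density comparisons.

## Strain rates and the decomposition

Between consecutive frames (interval Δt, minutes), half-links are
classified as conserved, appeared or disappeared using the cell lineage.
The deformation gradient of an ROI is the least-squares affine transport of
its conserved half-links, F̂ = B C⁻¹ with C = Σ(ω/2) l⊗l and
B = Σ(ω/2) l′⊗l, exact whenever the transport is affine, and the symmetric
tissue strain rate is Ĝ = (F̂ᵀF̂ − I)/(2Δt). Rotation (the antisymmetric
part of ∇v) is reported as a diagnostic but is not part of the
decomposition; the method does not account for rotational deformation, and
on rotating anisotropic tissue the two strain routes disagree by a term
proportional to rotation × texture anisotropy.

Non-conserved links are attributed to events. Under the default
division-priority rule, all links lost by a mother and gained by her
daughters (including the daughter–daughter link) are division links; links
exchanged between surviving cells are rearrangements; the links of a dying
cell and the new contacts closing its vacancy are apoptosis links (the
closing contacts are configurable to R). An alternative rule that re-labels
the re-pointed mother→daughter neighbor links as rearrangements is
implemented for comparison; it measurably degrades the cell-number balance
on dividing tissue, which is the reason division-priority is the default.

For each event class X ∈ {R, D, A}, the texture change attributed to X under
the intensive normalization is

    ΔM̂_X = [ Σ_app (ω/2) l′⊗l′ − Σ_dis (ω/2) l⊗l − M̂_mid·ΔN_h,X ] / N̄_h,

where N̄_h = (N_h(t) + N_h(t+Δt))/2 and ΔN_h,X is the half-link count change
caused by X. The −M̂_mid·ΔN_h,X term is the normalization transfer: an event
that changes the number of half-links changes M⁽¹⁾ through the denominator
as well as through the links, and both effects belong to the event's rate.
Without it, the measured Tr D̂ on dividing tissue can take the wrong sign
and the density balance fails by a factor ≈ 3 (the per-half-link mean of
(ω/2) l⊗l is M̂⁽¹⁾ itself, so the raw appeared-minus-disappeared sum is
dominated by the count change, not the shape deficit). For the extensive
M⁽⁰⁾ no transfer term exists — reproducing, as a measurable property, the
failure of the unnormalized tensor on division-containing ROIs.

The symmetric rate is recovered through the Sylvester relation
ΔM̂_X = −(X̂ M̂_mid + M̂_mid X̂)Δt with M̂_mid the mid-interval tensor
(centered differencing; the solution is unique and symmetric for positive
definite M̂_mid, via `scipy.linalg.solve_sylvester`). The sign follows the
kinematic equation below: divisions shrink the texture but contribute
positive tissue-growth rate, Tr D̂ ≥ 0, and apoptoses the reverse,
Tr Â ≤ 0. D̂_T = R̂ + D̂ + Â.

Cell shape change closes the decomposition Ĝ = Ŝ + R̂ + D̂ + Â. In
"strict" mode Ŝ ≡ Ĝ − D̂_T and the closure is exact by construction. In
"raw" mode (default) Ŝ is measured independently from the total texture
change via the unique SPD transport P solving P M̂_t P = M̂_t + ΔM̂_total,
with Ŝ = (PᵀP − I)/(2Δt) — the same multiplicative form as Ĝ, so the
reported closure residual is the genuine disagreement between the
deformation-gradient route and the texture route (zero to machine precision
for affine irrotational transport, O(Δt²) on smooth flows, finite where
rotation or strong spatial inhomogeneity makes the two weighted averages
differ). An additive (Sylvester) conversion of Ŝ was rejected because it
differs from Ĝ at first order in Δt even on ideal data, which would bury
the signal the residual is meant to expose.

## Kinematic validation

The continuum model ties the coarse-grained shape tensor to the tissue flow:

    dM/dt = (∇v − D_T) M + M (∇v − D_T)ᵀ,
    ∂ρ/∂t + ∇·(ρv) = (Tr D_T) ρ,       Tr R = 0.

Both are parameter-free and must hold for correctly measured quantities.
`kinematics.kinematic_check` evaluates the first equation per (ROI,
interval) as ΔM̂ vs [(∇v − D̂_T)M̂ + M̂(...)ᵀ]Δt; the neglected term is
O(Δt²) and is verified to scale with log-log slope 2. ∇v can come from the
texture route ((F̂ − I)/Δt), from the ground-truth flow, or from PIV.
`density_balance` evaluates the second as (Δρ̂/ρ̂_mid)/Δt + ∇·v vs Tr D̂_T
with ∇·v from Tr Ĝ or from the velocity field. All time derivatives are
Lagrangian: ROIs are sets of cells (plus their daughters, minus apoptotic
cells) tracked through the lineage, so per-ROI finite differences are
material derivatives and no Eulerian grids enter. Kymographs and moving
averages default to the reference geometry (200-px windows at 50-px steps;
30-min and 3-min time windows, centered).

## Cell tracking

Velocities are estimated by single-pass FFT cross-correlation PIV
(normalized windows, 64 px with 16-px steps by default, three-point
Gaussian sub-pixel peak fit, n = 3 standard-deviation outlier filter with
local-median replacement, flat windows masked invalid). Centers advected by
the velocity field are matched by an exact global linear assignment on
squared center distance (`scipy.optimize.linear_sum_assignment`), with
pairs beyond a cutoff forbidden and a dummy column per cell at the cutoff
cost so that cells may remain unmatched. The cutoff defaults to the
reference value of 400 px for real-scale images; on synthetic scenes the
pipeline uses 0.8 cell diameters — the penalty must sit below the neighbor
spacing, otherwise a chain of neighbor-to-neighbor mismatches around a
division or extrusion site can undercut a single no-match penalty. Each
appearing cell is resolved as a daughter of the neighboring matched cell
with the largest area decrease (ties: smallest center distance, then lowest
id); disappearing interior cells are apoptoses; disappearing outermost
cells are recorded as having left the field. No interactive track editing
is provided; a corrected lineage can be supplied programmatically.

## The synthetic tissue generator

Scenes are shared-vertex polygonal tilings — regular hexagonal lattices or
Lloyd-relaxed Voronoi tessellations of a rectangle (generators mirrored
across the box edges, so the cells partition the rectangle exactly and
adjacency is read off the shared Voronoi vertices). Flows are affine
(constant or time-varying velocity gradient, exact link transport
F = I + ∇v·Δt) or bilinear grids. Events are applied instantaneously after
advection, at most one per cell per interval, and at least two cells apart
so their local relaxations do not interact:

- T1: an interior short junction flips; the two cells across it lose
  contact and the two at its ends gain it. With the area-preserving
  relaxation flag the gaining cells' neighborhoods are translated until the
  gained center link equals the lost one in the mid-interval texture metric
  (|l|²_W with W = M̂_mid⁻¹), which is the exact condition for the event's
  contribution to Tr(M̂⁻¹ΔM̂_R) — and hence to Tr R̂ — to vanish in
  anisotropic tissue. Euclidean length matching is insufficient: the gained
  link is rotated ~90° from the lost one, and under shear it lands on the
  texture's minor axis, producing a systematic spurious Tr R̂.
- Division: the cell is cut by a line through its centroid, by default
  perpendicular to its long axis (random orientation available); daughters
  get fresh ids and the shared new edge; neighbors inherit the new vertices.
- T2/apoptosis: the cell's boundary collapses to its centroid; neighbors
  absorb the area exactly and all meet at the collapsed vertex, so
  non-consecutive ring neighbors become ω = 1/2 vertex contacts.

Default scene conditions: cells of ~20 px diameter (400 px² mean area,
matching the reference imaging scale of tens of pixels per cell), intervals
of 1–5 min, flows of |∇v| ~ 0.005–0.012 min⁻¹ so per-interval strains stay
in the small-deformation regime, event rates of ≤ 5% of cells per interval,
and 120×120-px Lagrangian ROI tiles (≈ 30–40 cells each). Label images are
rasterized deterministically with 1-px contours drawn on the geometric
edges (pixel centroids are then unbiased estimators of polygon centroids;
lattices aligned with the pixel grid can still reach the ~0.5-px
quantization limit).

What the generator does not emulate: mechanical force balance (no vertex
model energy; relaxations are geometric), curved cell edges, segmentation
errors and membrane-signal noise, out-of-plane tissue motion, and temporal
continuity of events (events are instantaneous). Passing tests therefore
demonstrate the correctness of the measurement pipeline on ideal segmented
geometry with known ground truth — not robustness to segmentation noise,
which on real movies is handled upstream of this package.

## Numerical choices and degenerate inputs

- Tensors are computed in px² and converted to physical units only at
  reporting (pixel_size in µm/px).
- ROIs with fewer than 3 non-collinear half-links are flagged degenerate
  and excluded from all tensor statistics; F̂ additionally requires a
  conserved-link matrix with condition number below 10¹².
- Eigenvalues are always ordered λ₁ ≥ λ₂; isotropic tensors return an
  explicit isotropy flag instead of an arbitrary orientation.
- Links censored by ROI boundaries or outermost-status changes (pair
  persists but the link leaves the measurable set) are discarded and
  counted, never guessed.
- PIV vectors are masked, never silently zero-filled; sampling a masked
  region falls back to the nearest valid vector and logs it.
- Regression diagnostics are per-component ordinary least squares without
  errors-in-variables correction; the validation targets identity-line
  agreement, not calibrated slopes.

## Known limitations

- Rotational deformation is excluded from the decomposition by design;
  strongly rotating anisotropic tissue inflates the raw-mode closure
  residual.
- The division-priority/alternative comparison covers the two published
  assignment conventions only; other conceivable rules are not enumerated.
- The M⁽³⁾/M⁽⁴⁾ variants ship unconfigured.
- Tracking assumes displacements small relative to cell spacing after
  advection; there is no gap closing or multi-hypothesis tracking.
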