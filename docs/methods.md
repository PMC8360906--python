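# Methods

## The model

`epistrain` simulates an epithelial monolayer as a two-dimensional vertex
model: the apical surface is a polygonal tiling of a periodic rectangle
whose degrees of freedom are the tricellular-junction positions. Every cell
carries the dimensionless mechanical energy

    U = (A − 1)² + (Γ/2) (L + Λ/(2Γ))²

where `A` and `L` are the cell's area and perimeter, `Γ` is a cortical
contractility/stiffness coefficient and `Λ` a line-tension-like parameter
that sets the preferred perimeter `L0 = −Λ/(2Γ)`. The defaults
`(Λ, Γ) = (0.259, 0.172)` are values previously fitted to the *Xenopus
laevis* animal-cap epithelium. Mechanical equilibrium is the minimum of the
total energy summed over cells with respect to all vertex positions.

A hyper-contractile (kRas^V12-like) cluster is modelled by replacing `Γ`
with `(1 + c)·Γ` in the flagged cells, where `c` is the *contractility
increment* (`c = 0.09` means a 9% increase). The substitution applies to
every occurrence of `Γ` in the cell's energy, so the cluster cells' whole
perimeter elasticity — including the preferred-perimeter term — stiffens.

The cell-level isotropic stress is

    Peff = A − 1 + Γ L²/(2A) − Λ L/(4A)

with positive values indicating net tension and negative values net
compression. Only this isotropic component is computed; the full deviatoric
stress tensor is out of scope.

## Simulation pipeline

1. **Generation.** Uniform random points in a square periodic box of area
   `n_cells` are tessellated (Voronoi of a 3×3 tiling) and smoothed with 4
   Lloyd steps. The mesh is generically trivalent; duplicated junction
   images across tile copies are merged with a periodic KD-tree at
   `1e-7·L`, far above the `~1e-12·L` floating-point scatter of copies and
   far below real junction separations.
2. **Relaxation.** L-BFGS-B with the analytic energy gradient (derived from
   the shoelace area and edge-length sums with minimum-image unwrapping)
   down to a maximum per-vertex gradient norm of `1e-6`, with up to 5
   memory-reset restarts. Edges shorter than 0.05 mean edge lengths undergo
   T1 neighbour exchanges (new edge at 1.5× the threshold, perpendicular);
   descent then continues. At these parameters a triangle's energy
   decreases monotonically as it shrinks, so T1 cascades can leave a
   collapsed triangle on which no T1 applies; such triangles are removed by
   a T2 move (cell collapsed to a single vertex). The T2 is numerical mesh
   maintenance — the simulator models no division, apoptosis or extrusion.
3. **Zero net stress.** The box is rescaled isotropically, re-relaxing at
   each scale, until the cell-area-weighted mean `Peff` is within `1e-4` of
   zero (bisection). At mean cell area 1 the tissue is strongly tense
   (mean `Peff ≈ +0.95`); the zero crossing sits near mean cell area 0.27.
   The bisection bracket `[0.8, 1.2]` is therefore applied *relative to the
   closed-form zero-stress scale of a regular hexagon* under the same
   `Peff` expression, which brackets the disordered-tissue zero robustly.
4. **Cluster.** The cell nearest the box centre plus successive adjacency
   rings are flagged until at least `cluster_size` cells (default 19 ≈ a
   centre cell with two full rings, the visual scale of experimental
   clusters) are in the cluster; their `Γ` multiplier is set to `1 + c` and
   the tissue re-relaxed.

Defaults: 400 cells for single-tissue analyses; sweep-scale studies use
300-cell tissues, large enough to populate the 7+ ring category while
keeping grid searches affordable.

## Shape, orientation and division measures

Cell shape uses the second-moment tensor of the junction positions about
their arithmetic-mean centroid, `S = (1/n) Σ (Rᵢ − C)(Rᵢ − C)ᵀ`. The long
axis is the principal eigenvector of `S`; *circularity* is the eigenvalue
ratio `λmin/λmax` (1 for a perfect circle). Cells whose relative eigen-gap
is below `1e-6` have no defined axis and are excluded from orientation
statistics (exclusions are counted, not imputed).

Orientation relative to the cluster is the acute angle (0–90°) between the
long axis and the line from the cell centroid to the *nearest point on the
cluster's outer boundary* (fallback: direction to the cluster centroid when
the nearest point is ambiguous). Division orientation applies the same
reference to the anaphase daughter-nuclei separation axis; out-of-plane
divisions are counted separately, never angled. The division rate is the
percentage of cells dividing per minute, `100·n_div/(n_cells·minutes)`.
Host cells are grouped by breadth-first graph distance on the
cell-adjacency graph (shared walls) into rings, and rings into the
categories 1–3, 4–6 and 7+; graph distance, not Euclidean distance, matches
the "cells away from the cluster" convention. Rose histograms bin angles
into nine 10° bins, right-open except the final bin (90° falls in
[80, 90]).

## Contractility inference

Orientation angles pooled per category form an empirical distribution; the
experiment and a simulation are compared per category with the 1D
Wasserstein distance (the area between the two ECDFs, in degrees;
`scipy.stats.wasserstein_distance`), and the three category distances are
summed without normalisation. The cluster increment is estimated by grid
search over `c ∈ [0, 0.20]` in steps of 0.01: for each grid value the
simulator produces tissues at that increment (one per seed, pooled), and
the increment minimising the summed distance wins, ties going to the
smaller increment. Simulation per seed reuses a cached zero-net-stress base
tissue, so only the cluster perturbation and final relaxation are redone
per grid point.

**Replication sizing.** Cells within one tissue share its quenched
disorder, so the effective sample size of a pooled orientation distribution
is the number of tissues, not cells. With 5 tissues per side the argmin of
the summed-distance curve fluctuates with a standard deviation of ≈ 0.03 —
three grid steps. Recovery studies therefore use 20 simulation seeds per
grid point and 10 pseudo-embryos, which brings the grid-search Monte Carlo
error under the grid step; the plain `contractility_sweep` default remains
5 seeds for interactive use.

## Synthetic pseudo-experiments

The generators stand in for confocal-derived measurements and are
deterministic functions of `master_seed`:

- **Tracings** run the full simulation pipeline per pseudo-embryo at a
  chosen true increment and export every cell polygon in a seam-free frame
  centred on the cluster (cells wrapping the periodic seam are dropped,
  emulating a bounded field of view). Isotropic Gaussian jitter of 2% of
  the mean edge length is added to each junction once — shared by
  neighbouring cells, like a manual tracing error. What this does *not*
  emulate: segmentation bias, embryo curvature, or non-stationary
  illumination; passing recovery here shows the inference machinery is
  consistent, not that real tracing noise is this benign.
- **Recoil traces** follow the Kelvin-Voigt step response
  `d(t) = d0 + D(1 − e^{−kt})` plus i.i.d. Gaussian noise, sampled every
  4 s (the imaging frame interval) with 16 post-ablation and 2 baseline
  frames. Default `k = 0.1 s⁻¹` (half-life ≈ 7 s) is chosen so the 4 s
  sampling resolves the relaxation — a faster junction (`k ≥ 0.5 s⁻¹`)
  would saturate within a frame and leave `k` unidentifiable at this frame
  rate. Group amplitudes default to a hyper-contractile cluster recoiling
  about twice as far as controls with identical `k`.
- **Divisions** draw event counts from a Poisson law at a configurable
  rate (default 0.2%/min over 100 cells for 30 min), positions in an
  annulus around a circular cluster, and axis angles from an axial von
  Mises law (doubled-angle concentration `κ`; `κ = 0` is uniform on
  [0°, 90°]).

## Kelvin-Voigt recoil fitting

The flanking-vertex separation after junction ablation is fitted with
`d(t) = d0 + D(1 − e^{−kt})` by nonlinear least squares; `d0` is fixed to
the pre-ablation baseline mean by default (a free-`d0` mode exists).
Initial guesses derive from the trace (amplitude from the total rise, `k`
from the half-rise time); `k` is bounded to `[1e-4, 10] s⁻¹`. The initial
recoil velocity — the tension proxy — is `d'(0) = D·k`. A negative fitted
amplitude is flagged rather than rejected (compressed junction or failed
ablation). The module reports `k` alongside initial recoil and draws no
mechanical conclusion from either.

## Numerical choices and degenerate inputs

- Periodicity: all geometry uses minimum-image displacements; energies and
  gradients are exactly translation invariant.
- Unit edge vectors are guarded against zero length (`max(‖e‖, 1e-300)`);
  topological moves remove genuinely collapsed elements.
- Grid-search ties: smallest increment (parsimony). Argmin over NaN-marked
  failed grid points ignores them; a failure is recorded, never silently
  dropped.
- Angles are degrees in every file format; radians appear only inside
  trigonometric internals. Tracing tables in image (y-down) pixel
  coordinates can be flipped on load.
- Empty samples, missing ring categories, non-simple polygons, decreasing
  timestamps and out-of-range angles raise typed errors naming the
  offending cell, category or row.

## Known limitations

- Quasi-static only: no dynamics, no division/extrusion mechanics, no
  boundary effects (periodic box).
- `Peff` is the isotropic stress; the radial *anisotropic* stress around a
  contractile cluster appears in `Peff` only as a weak near-field excess
  (the long-range signature lives in cell orientation, which is what the
  inference uses).
- The far-field (7+) orientation distribution in finite periodic tissues
  shows a mild tangential bias from the cluster's periodic images; it
  affects experiment and simulation identically and therefore cancels in
  the Wasserstein comparison.
- Pseudo-embryos are i.i.d. seeds; real embryo-to-embryo variability
  structure is unknown and not modelled.
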