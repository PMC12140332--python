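# Methods

`softinverse` recovers hidden physical parameters of soft bodies — material
moduli M, and the position P and shape S of a stiff internal abnormality —
by matching observed surface keypoint trajectories D against the output D̂
of a finite-element virtual twin, minimizing

    L(M, P, S) = ‖D − D̂(M, P, S)‖²   (squared Euclidean norm over all
                                       steps, keypoints and components)

with a gradient-free batch Bayesian optimizer.  This note records the model,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Constitutive model

All bodies are incompressible Neo-Hookean, energy density
W = (μ/2)(λ₁² + λ₂² + λ₃² − 3) with μ = E / (2(1+ν)) and ν = 0.5.  Exact
incompressibility cannot be imposed in a displacement-only FE formulation,
so the solids use the nearly-incompressible decomposition
W = (μ/2)(J^(-2/3) I₁ − 3) + (κ/2)(J̄ − 1)² with κ evaluated at an
effective ν = 0.499 (κ/μ ≈ 500, volumetric error of order μ/κ ≈ 0.2 %).
The exact-incompressible principal-stretch form (σᵢ = μλᵢ² − p) is kept as
the analytic oracle; note that the consistent second Piola-Kirchhoff tensor
of this energy is S = μI, i.e. σ = μFFᵀ − pI, which is what the classical
uniaxial solution σ₁₁ = μ(λ² − λ⁻¹) requires.

A Saint Venant-Kirchhoff law (S = λ tr(E) I + 2μE) is available for the
cross-model generality fixture.  Because StVK loses ellipticity under
strong compression, that fixture runs the StVK side at a moderately
compressible ν_eff = 0.45; the recovery side still uses the
nearly-incompressible Neo-Hookean twin, so the test retains its
model-mismatch character.

## Elements

* **Solids** (beam): 8-node trilinear hexahedra, 2×2×2 Gauss quadrature,
  total-Lagrangian formulation, with a mean-dilatation treatment — the
  volumetric term is evaluated at the element-average Jacobian J̄ — to
  avoid volumetric locking at ν → 0.5.  The single-hex uniaxial test
  against σ_nom = μ(λ − λ⁻²) selects this scheme (within 1 %).
* **Thin structures** (balloon, valve): 3-node incompressible plane-stress
  Neo-Hookean membranes, energy per reference area
  T·(μ/2)(tr C₂ + 1/det C₂ − 3), no bending stiffness.  A membrane's
  stiffness depends on E and T only through the product AS = E·T (the
  arterial stiffness reported for the valve benchmark).  Pressure is a
  follower load along the deformed normal (required at large strain);
  rigid-body modes of the free-floating closed balloon are removed by
  nullspace (Lagrange) constraints, preserving the spherical symmetry of
  the homogeneous response.

Element residuals are analytic.  Hexahedral tangents are the exact
consistent linearization (deviatoric ∂P/∂F plus the mean-dilatation
rank-one volumetric terms); membrane tangents are assembled by per-element
finite differencing of the analytic residual (step 10⁻⁶ of the element
size).  Both are verified against global finite differences in the tests.

## Solvers

**Quasi-static** (balloon, valve): the load ramps linearly over `n_steps`
increments; each increment is solved by damped Newton (backtracking line
search, halving, 8 trials) with automatic increment halving down to 1/64 of
a step on failure.  Convergence: relative residual 1e-8, or the roundoff
floor of the assembled residual (50·ε times the pre-cancellation force
magnitude — the binding limit when a region is 10⁶× stiffer than its
surroundings), or a vanishing Newton update (1e-10 relative).

**Dynamic** (beam): displacement-driven quasi-statics is scale-invariant in
the moduli — the equilibrium displacement field depends on E_a/E_b only —
so a static virtual twin cannot identify absolute moduli of the beam at
all.  Identifiability comes from inertia: the beam cases integrate
ρü = ∇·σ with an implicit Newmark scheme (γ = 0.6,
β = (γ+1/2)²/4 ≈ 0.30, mildly dissipative to damp mesh-frequency ringing),
lumped (row-sum) mass with the benchmark density ρ = 1 kg/mm³, and the
30 mm end-face ramp applied over a total time of 60 s — about the transit
time of the base material's shear wave (√(E_b/ρ) = 1 mm/s) across the
beam, so transient lag is a strong function of both absolute moduli.  The
ramp duration is a fixture constant of the benchmark.  Adaptive substep
halving (floor 1/32) handles stiff candidates.  No physical damping is
applied; none is part of the model.

A failed forward solve inside the inverse loop is recorded as +∞ loss and
the run continues; very soft candidates legitimately fail (e.g. membrane
pressures beyond the Neo-Hookean limit point P* = 2μ(t/R)·0.620).

## Benchmarks (synthetic-data generator)

Observations are generated by the package's own forward solver at the
printed ground truths — deliberately an "inverse crime": the benchmark
isolates the optimizer's ability to invert the map, with a perfectly
specified model.  Optional additive Gaussian noise (σ = fraction × max|D|,
applied to post-initial frames) probes robustness to observation error.
What these benchmarks do **not** probe: model error (except the StVK
cross-model fixture), boundary-condition mismatch, or tracking artifacts of
real video — all present in physical experiments.

* **Beam**: 50×25×3 mm, E_b = 1e3 Pa, brick inclusion E_a = 1e6 Pa spanning
  the cross-section over x ∈ [30, 50] mm (center C = 40, half-width
  W = 10), left face clamped, right face translated (0,0,+30) mm.  Four
  keypoints on the long edge at x = 10, 20, 30, 40 mm, all three
  components tracked.  Search bounds: E ∈ [1e2, 1e10] Pa (log10-encoded),
  C ∈ [0, 50], W ∈ [0, 25] mm.
* **Balloon**: closed membrane sphere, mid-surface radius 100 mm,
  t = 3 mm, inner pressure 8 Pa (chosen to reach stretch λ ≈ 1.10,
  safely below the λ = 7^(1/6) limit point; the pressure magnitude is a
  package assumption).  Abnormality: intersection with the revolved
  generator R(θ) = R₀(1 + C₁cos4θ + C₂cos8θ) about the z-axis of the
  offset frame (θ the polar angle from +z; membership ρ ≤ R(θ), boundary
  inclusive), truth R₀ = 41.2, C₁ = 0.47, C₂ = −0.35,
  P = (−4.5, 62.1, 65.7) mm.  All vertices tracked.  The position bounds
  are ±200 mm so the truth lies strictly inside the box.
* **Valve** (simplified): a hemispherical membrane dome of radius
  r_co = 12.5 mm stands in for the tri-leaflet geometry — the equator ring
  plays the leaflets' fixed lower edges, the dome the coapting belly — and
  a 5 kPa trans-valvular pressure inflates it (both r_co and the pressure
  are package assumptions, overridable).  Healthy AS_b = 1e6 Pa × 0.3 mm;
  calcified patch AS_a = 1e9 Pa × 0.9 mm with its own revolved-generator
  shape.  The three most-displaced points of the upper half (selected on
  the ground-truth motion) are tracked.  Since membranes feel only E·T,
  results are reported as AS; E and T are not separately identifiable here.

Abnormal elements are those whose centroid lies inside the generator
(boundary inclusive), which makes labelled counts exact; consequently the
loss is piecewise-constant in the shape parameters at fixed labels, and
shape recovery is reported through mask SSIM rather than parameter errors.

Each case carries a `"paper"` mesh preset (the printed resolutions, e.g.
20×6×4 beam hexes) and a coarser `"desk"` preset (5×2×2 beam, icosphere
refinement 2, 5-ring dome; 5 output frames) used for the minute-scale
benchmark runs; the preset is stamped into every result.

## Optimizer

Batch-sequential efficient global optimization: seeded Latin-hypercube
initial design (n₀ = 2d + 2 by default) in unit-encoded coordinates
(moduli log10-encoded over their 8–9 decade ranges, geometry linear);
random-forest surrogate (100 bootstrapped trees, tree-spread variance,
s ≥ 1e-12); MGF acquisition

    M(x, t) = Φ((L_min − L̂′)/s) · exp((L_min − L̂ − 1)t + s²t²/2),
    L̂′ = L̂ − s²t,

evaluated in log space (log Φ + clipped exponent).  At t = 0 it reduces
exactly to the probability of improvement.  Each iteration draws q
temperatures t ~ Lognormal(0, 1) (a fixed-t mode, default t = 2, is also
available; the two conventions coexist in the source method and both are
kept) and maximizes the q criteria with (μ+λ) evolution strategies
(μ = 4, λ = 28, 50 generations, self-adaptive per-dimension Gaussian
steps) run in lockstep so the forest is queried once per generation.

Two design choices matter for endgame precision:

* losses are modelled as log10(L + 1e-300) — a strictly monotone transform
  that leaves the argmin unchanged but resolves the many-decade dynamic
  range near the optimum far better than the raw scale;
* the archive-seeded ES parents (and the re-mutation of duplicate
  proposals) use step sizes set to the incumbent's distance to the nearest
  archive point of *meaningfully different* objective value (> 0.1 % of
  the transformed-loss spread) — a self-shrinking trust region that tracks
  the resolved structure of the landscape and cannot collapse onto
  near-duplicate re-evaluations of the incumbent.  On a 4-d quadratic at
  the beam-benchmark budget this improves the final coordinate error from
  ~2e-2 to ~1e-7 of the range;
* one member of each batch (when the archive exists and q ≥ 2) is a
  multi-scale local search around the incumbent, at a radius drawn
  log-uniformly between that refinement scale and a tenth of the range.  A
  piecewise-constant forest cannot extrapolate a descending trend past the
  sampled cluster — pure acquisition maximization then crawls along leaf
  boundaries — and this member supplies the missing trend evidence at all
  scales.

Evaluations within a batch may run concurrently (joblib); results are
identical to sequential evaluation for a deterministic objective.  A run
stops at the evaluation budget or when the best loss falls below
1e-12·(1 + ‖D‖²).  Failed evaluations enter the archive as +∞ and are fed
to the forest two decades above the worst finite loss.

## Shape scoring

Balloon: equirectangular raster (default 128², recorded in the mask) of
the northern hemisphere, each pixel labelled by the nearest
surface-element centroid direction; truth and estimate are labelled on the
same mesh.  Valve and other point clouds: abnormal-element centroids
projected on the two leading principal axes fitted to the union of both
sets (axis signs fixed by the first point's loadings, removing the PCA
reflection ambiguity).  Masks are compared with SSIM (Gaussian window
σ = 1.5, K₁ = 0.01, K₂ = 0.03, dynamic range 1 — the canonical constants);
identical masks score exactly 1.  Absolute SSIM values depend on raster
resolution and window, so those parameters are always reported alongside.

## Known limitations

* The valve geometry is a deliberate parametric simplification; it
  preserves the stiffness-recovery mechanism (membrane under trans-valvular
  pressure, fixed lower edges) but not leaflet coaptation or bending.
* Membranes make E and T individually unidentifiable (only AS = E·T).
* A region ~10³× stiffer than its surroundings deforms negligibly, so its
  modulus is identifiable only through residual compliance — a nearly flat
  loss direction; recovery there leans heavily on the optimizer's local
  refinement and on the noise-free inverse-crime setting.
* Quasi-static displacement-driven problems identify modulus ratios only;
  the beam benchmark's absolute moduli are identifiable solely because the
  twin is dynamic.
* No contact, self-contact, fluid-structure interaction, viscoelasticity,
  anisotropy, or damage.

The scaled-down acceptance runs use the desk presets with q = 8 and, for
the beam, balloon and valve benchmarks respectively, at most 80, 60 and 40
batch iterations (problem sizes chosen so each run completes in minutes on
one CPU).  At this scale the beam moduli recover to ~1e-4 %, while the
balloon shape search reliably stalls in a mimicking local family (a large
far-centered generator whose intersection footprint overlaps the truth
patch) and the valve's calcified-patch stiffness resolves only to within a
factor of a few — both consequences of evaluation volume and of the
near-rigid-inclusion flatness discussed above, not of the formulation.
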