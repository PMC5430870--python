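# Methods

## Model

`gliosim` integrates a reaction-diffusion model of post-surgery glioma
growth on a voxel grid. The tumor cell density `u(x, t)`, expressed as a
fraction of the tissue carrying capacity (`u ∈ [0, 1]`), evolves as

    ∂u/∂t = ∇·(D̄(x) ∇u) + ∇·(D̂ ∇σ) + u [ (ρ − r(x,t)) (1 − u) − k̄(x,t) ]

with no-flux (Neumann) conditions at the brain boundary. The terms are:

- **Anisotropic diffusion.** `D̄(x)` is built from a DTI-like tensor field:
  in white matter (WM) the DTI eigenvector frame is kept and the
  eigenvalues are replaced with `(e₁ D_WM, D_GM, D_GM)`, where `e₁` is the
  normalized largest DTI eigenvalue, so migration is fastest along the
  fiber direction; gray matter (GM) is isotropic `D_GM·I`; CSF, the
  resection cavity and extracranial space carry the zero tensor (glioma
  invasion stops at CSF). A DTI-free variant replaces the tensor by the
  scalar map `D_WM`/`D_GM` per tissue.
- **Logistic proliferation** at rate `ρ`, saturating at carrying capacity.
- **Radiotherapy.** Linear-quadratic survival `S = exp(−αd − βd²)` per
  fraction of dose `d`; on fraction days the kill rate is `r = 1 − S`,
  entering the logistic-shaped loss `r·u(1−u)` (so near-capacity cores are
  radio-insensitive in this formulation). Between fractions `r = 0`.
- **Chemotherapy.** First-order kill `k̄·u` with a tissue-dependent rate:
  the nominal `k` in GM, and `k/(k + ω)` in WM, where `ω ∈ [0,1]` is the
  local WM proportion in a cubic window (side `2r+1`, default `r = 1`);
  tissue heterogeneity modulates drug absorption. The WM branch is
  implemented literally; note that for `ω ≪ 1 − k` it *exceeds* `k`.
- **Viscoelastic stress.** Brain tissue is a generalized Maxwell
  (Maxwell-Weichert) solid: `n` spring-dashpot elements in parallel with a
  free spring, relaxation modulus `E(t) = Σ E_k e^{−t/τ_k} + E_∞`,
  `τ_k = η_k/E_k`. Stress follows strain history through the Boltzmann
  hereditary integral and feeds back on the density through
  `∇·(D̂ ∇σ)` with `D̂` a diagonal tensor with negative entries.

Neither therapy acts in the resection cavity. Tumor may diffuse into and
proliferate in the cavity (both configurable); density is pinned to zero
in CSF and outside the brain.

## Default parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `D_GM` | GM diffusivity | 0.0013 | cm²/day |
| `D_WM` | WM diffusivity | 5·`D_GM` | cm²/day |
| `ρ` | proliferation rate | 0.012 | day⁻¹ |
| `α` | LQ linear coefficient | 0.027 | Gy⁻¹ |
| `α/β` | LQ ratio (β derived) | 10 | Gy |
| `k` | chemotherapy kill rate | 0.0196 | day⁻¹ |
| `n` | Maxwell elements | 1 | — |
| `E₁` | Maxwell spring modulus | 3156 | Pa |
| `E_∞` | free-spring modulus | `E₁`/6 | Pa |
| `η₁` | Maxwell viscosity | 8.9×10⁻⁸ | Pa·s |
| `D̂` | stress diffusion | −10⁻¹⁴ | cells/(Pa·day) |
| `u_detect` | imaging detection threshold | 0.4 | — |
| `κ` | strain per unit density | 0.01 | — |

These are the consensus low-grade-glioma values used across the
reaction-diffusion literature. Diffusivities are converted to mm²/day
internally (×100), since voxel spacing is carried in mm. Standard
calendars: radiotherapy 30 consecutive daily fractions of 2 Gy (60 Gy
total); chemotherapy 6 cycles of 5 active days with a 28-day period
(30 active days over 145 days). Whether fractions skip weekends is not
standardized here; consecutive days are the default and the calendar is
fully overridable.

Two literal-parameter consequences worth knowing:

- `τ₁ = η₁/E₁ ≈ 2.8×10⁻¹¹ s ≈ 3×10⁻¹⁶ days`: the Maxwell element relaxes
  instantaneously on the day scale of tumor growth, so the hereditary
  integral tracks `E₁·g(t)` exactly (the recursion handles this limit
  without underflow problems). Combined with `|D̂| = 10⁻¹⁴`, the stress
  term is ~10 orders of magnitude below the other terms — consistent with
  viscoelasticity having no significant effect on growth contours at
  these parameter values.
- With `α = 0.027 Gy⁻¹` and 2 Gy fractions, `r = 1 − S ≈ 0.063 day⁻¹`
  exceeds `ρ = 0.012 day⁻¹`: the modeling assumption that treatment is
  weaker than proliferation is violated by the standard parameters
  themselves. The solver warns (once per run) and remains stable; the
  assumption is advisory, not enforced.

## Numerics

- **Spatial discretization.** `∇·(D̄∇u)` is computed in conservation
  (flux) form: per axis, face fluxes combine the diagonal tensor entry
  (face-averaged) with the off-diagonal cross terms evaluated from
  central differences that use reflective ghosts at the brain-mask
  boundary. Because the update telescopes face fluxes and faces crossing
  the mask boundary are closed, total mass is conserved to floating-point
  rounding under no-flux, and with a diagonal tensor the stencil reduces
  exactly to the standard 7-point variable-coefficient scheme.
  Anisotropic voxel spacing (e.g. 0.47×0.47×6.5 mm) is supported in all
  stencils. The scheme is validated by symmetry (axis permutation and
  mirror), reduction, and conservation oracles rather than claimed
  identical to any published stencil variant.
- **Time stepping.** Forward Euler with
  `dt ≤ 0.9 / Σ_axis (2 D_max / h_axis²)`, `D_max` the largest tensor
  eigenvalue on the grid — the standard sufficient bound for explicit
  diffusion. Densities are clipped to [0, 1]; clipping events beyond
  1×10⁻¹² are counted per step and reported in the run log. With smooth
  initial data the count is zero over ≥10⁴ steps on random anisotropic
  phantoms; a discontinuous u=1 ball seed produces a short (~10-step)
  transient of undershoots at the seed edge, which is an artifact of the
  initial condition, not of the scheme (a `smooth_sigma` option on the
  seeder exists for studies where this matters).
- **Hereditary integral.** One recursive exponential accumulator per
  Maxwell element, exact for piecewise-linear strain histories; memory is
  independent of history length. `1 − e^{−λ}` is evaluated with `expm1`
  and the ramp weight switches to its series limit for `λ < 10⁻⁸`.
- **Boundary handling.** The no-flux statement and the
  zero-boundary-concentration statement are satisfied simultaneously:
  diffusivity is zero outside the brain mask (no flux crosses it by
  construction) and `u` is pinned to 0 in CSF/outside voxels.
- **Stress formulation.** The Boltzmann integral consumes a
  strain-derived operand. The primary (`normal_stress`) formulation
  applies the hereditary functional to the volumetric strain proxy
  `ε = κ·u` and takes `∇·(D̂∇σ)` of the resulting scalar stress; the
  `gradient` formulation applies it to the components of `∇ε` instead.
  For spatially uniform moduli the hereditary operator commutes with the
  spatial derivatives, so the two formulations agree analytically; both
  are exposed because the physical origin of the strain and the
  scalar/vector status of σ are genuinely open modeling choices. The
  strain proxy `ε = κ·u` itself is the minimal density-to-strain coupling
  (the model consumes strain but does not define its source); κ defaults
  to 0.01 and setting κ = 0 (or `D̂ = 0`) reproduces the stress-free
  solution bit for bit.

## Synthetic phantoms

Clinical post-surgery MR volumes cannot be shipped, so all tests and the
validation script run on parametric-analytic phantoms: an ellipsoidal
brain with a GM cortical ribbon (distance-transform shell), WM interior,
spherical CSF ventricles, an optional spherical resection cavity, and
straight fiber bundles that orient WM tensors (principal eigenvector
along the bundle tangent, anisotropy ratio relaxing to 1 with Gaussian
falloff — smooth tensor fields avoid discretization artifacts in solver
tests). Tensors are trace-normalized; label codes are fixed integers
(0 outside, 1 CSF, 2 GM, 3 WM, 4 cavity) as a file-level contract.

What the phantoms do **not** emulate: human anatomy, MRI intensities and
noise, registration/segmentation error, tumor-induced mass effect on the
anatomy, and realistic fiber-tract curvature. Passing tests therefore
demonstrate correctness of the numerics and internal consistency of the
model components on controlled geometry — not clinical accuracy, which
requires patient images the package does not ship.

## Validation quantities and problem sizes

`scripts/acceptance.py` recomputes, from scratch:

1. 0-D logistic integration vs the closed form (dt = 0.1, 1000 steps).
2. 1-D Fisher-KPP front speed vs `2√(Dρ)` on a 300 mm line (h = 0.5 mm)
   over 3000 days, measured between T/2 and T. The horizon is set by
   front physics: pulled fronts converge like `ln t / t` (Bramson
   correction ≈ 3% over this window; at 600 days it is ~14%, out of reach
   of any discretization).
3. Mass drift under pure diffusion on a 32³ phantom, 120 steps.
4. Maximum per-step deviation from an independently coded plain
   reaction-diffusion solver in the isotropic reduction (16³, 100 steps).
5. Viscoelastic recursion vs direct trapezoid quadrature on random
   piecewise-linear strain histories (relaxation times 0.5/1.5 days —
   chosen resolvable by quadrature; the default brain τ is exercised via
   its exact instantaneous limit in the unit tests).
6. Therapy monotonicity on a 48³, 2 mm-spacing phantom (96 mm domain,
   18 mm seed, 150 days, standard calendars): pointwise treated ≤
   untreated and treated u=0.4 contour contained in the untreated one.
   The coarse spacing buys a realistically sized domain at desk-scale
   cost; the 18 mm dense seed keeps the detection contour populated
   through the front-relaxation transient and therapy.
7. Dice/Jaccard identity `DC = 2·JS/(1+JS)`, `JS ≤ DC`, and threshold
   nesting on 200 random mask pairs.
8. Boundedness: zero post-transient clipping over 10⁴ explicit steps on
   20 random anisotropic 16³ phantoms (half with therapy calendars).

## Design notes and limitations

- Eigenvalue sorting in the tensor construction is descending with a
  stable tie-break (degenerate spectra keep the eigensolver's
  deterministic order, so an identity DTI maps to the coordinate basis).
- `e₁` is normalized by the maximum largest eigenvalue over WM voxels of
  the volume — a per-volume choice; per-voxel trace normalization is a
  plausible alternative and the choice is configurable at the DTI level
  (feed a rescaled field).
- Radiotherapy's per-fraction kill acts as a day-long loss rate by
  default (`rt_mode="rate"`), since the kill enters a rate equation; an
  instantaneous-kill mode (`u ← S·u` at fraction start) exists for
  sensitivity checks. No pharmacokinetics for chemotherapy: activity is
  binary per calendar day.
- The ablation harness scores variants against the full-model run (no
  clinical ground truth ships with the package), so its deltas measure
  component influence, not accuracy against patients; at desk scale the
  deltas are much larger than on clinical data, where tumors are large
  relative to the diffusion length.
- The both-empty-mask case raises an error rather than scoring 1, so
  degenerate scenarios fail loudly.
- No image preprocessing (registration, skull stripping, segmentation),
  no DICOM, no mesh mechanics or mass-effect displacement, no implicit or
  operator-splitting schemes.
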