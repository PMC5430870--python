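# gliosim

Simulation of post-surgery glioma growth under treatment, for researchers
modeling how residual low-grade glioma evolves after resection and how
radiotherapy and chemotherapy reshape the visible tumor contour on MR
images.

## Model

The tumor cell density `u(x,t) ∈ [0,1]` (fraction of carrying capacity)
follows a reaction-diffusion equation on the voxel grid of a labeled brain
volume:

    ∂u/∂t = ∇·(D̄(x)∇u) + ∇·(D̂∇σ) + u[(ρ − r(x,t))(1 − u) − k̄(x,t)]

- `D̄(x)`: anisotropic growth tensor built from DTI — in white matter the
  DTI eigenvector frame with eigenvalues `(e₁D_WM, D_GM, D_GM)`, isotropic
  `D_GM·I` in gray matter, zero in CSF/cavity/outside (invasion stops at
  CSF).
- `ρ u(1−u)`: logistic proliferation.
- `r = 1 − exp(−αd − βd²)` on radiotherapy fraction days (linear-quadratic
  survival), entering the logistic-shaped loss `r·u(1−u)`.
- `k̄`: chemotherapy kill on active days — `k` in GM, `k/(k+ω)` in WM with
  `ω` the local white-matter proportion (tissue heterogeneity modulates
  drug absorption).
- `σ`: viscoelastic stress from a Maxwell-Weichert (generalized Maxwell)
  model via the Boltzmann hereditary integral, fed back through the
  negative-diagonal stress-diffusion tensor `D̂`.

No-flux boundary at the brain surface; neither therapy acts in the
resection cavity. Simulated contours are thresholded at the imaging
detection level `u = 0.4` and compared with Jaccard (`JS`) and Dice (`DC`)
overlap. Defaults are the consensus low-grade-glioma parameters
(`D_GM = 0.0013 cm²/day`, `D_WM = 5·D_GM`, `ρ = 0.012/day`,
`α = 0.027/Gy`, `α/β = 10 Gy`, `k = 0.0196/day`); see
[docs/methods.md](docs/methods.md).

Because clinical MR data cannot ship with the package, a parametric
phantom generator provides labeled brain volumes (GM ribbon, WM interior,
CSF ventricles, resection cavity), fiber-aligned DTI-like tensor fields,
tumor seeds and the standard therapy calendars (60 Gy in 30 daily 2 Gy
fractions; six 5-day chemotherapy cycles every 28 days).

## Worked example

```python
import gliosim as g

spec = g.default_spec(shape=(48, 48, 48), with_cavity=True, seed=0)
spec.spacing = (2.0, 2.0, 2.0)              # 96 mm domain at 2 mm voxels
vol  = g.make_brain_phantom(spec)
dti  = g.make_tensor_field(vol, spec)
params = g.TissueParams()
dbar = g.build_growth_tensor(dti, vol, params)
init = g.seed_tumor(vol, center=(19, 24, 24), radius=18.0)  # 18 mm residual tumor

rt    = g.make_therapy_calendar("radiotherapy", start_day=0)
chemo = g.make_therapy_calendar("chemotherapy", start_day=0)
cfg   = g.SimulationConfig(t_end=150.0, save_every=50.0)

treated   = g.simulate(init, vol, dbar, params, cfg, rt_plan=rt, chemo_plan=chemo)
untreated = g.simulate(init, vol, dbar, params,
                       g.SimulationConfig(t_end=150.0, save_every=50.0,
                                          use_rt=False, use_chemo=False))

report = g.overlap_report(treated.final_mask, untreated.final_mask)
print(f"initial tumor volume: {init.total_mass():.0f} mm^3")
print(f"treated mask:   {report.n_pred} voxels")
print(f"untreated mask: {report.n_truth} voxels")
print(f"JS = {report.jaccard:.3f}, DC = {report.dice:.3f}")
```

Output:

```
initial tumor volume: 21512 mm^3
treated mask:   1097 voxels
untreated mask: 5379 voxels
JS = 0.204, DC = 0.339
```

After 150 days the treated tumor's visible (u ≥ 0.4) contour covers 1097
voxels and lies entirely inside the 5379-voxel untreated contour: therapy
shrinks the detectable tumor without changing where it can grow, and the
low overlap scores quantify how strongly the standard chemoradiotherapy
schedule separates the two outcomes in this scenario. A run also emits a
warning that the combined treatment rate exceeds the proliferation rate —
a literal consequence of the standard parameters, see the methods note.

The same pipeline is available from the shell:

```sh
gliosim phantom --shape 48 48 48 --seed 0 --out-dir ph/
gliosim simulate --labels ph/labels.nii.gz --dti ph/dti.nii.gz \
    --init init.nii.gz --rt-plan ph/rt_plan.json \
    --chemo-plan ph/chemo_plan.json --out-dir sim/
gliosim evaluate --pred sim/final_mask.nii.gz --truth truth.nii.gz --out report.json
gliosim ablate --scenario scenario.yaml --out table.csv
```

`ablate` re-runs a scenario with components switched off (no-chemo, no-RT,
no-treatment, no-DTI, no-viscoelastic) and tabulates the JS/DC decrease of
each variant against the full model.

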