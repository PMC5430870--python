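"""Explicit finite-difference integrator for the full growth PDE.

The model advanced here is

    du/dt = div(Dbar(x) grad u) + div(Dhat grad sigma)
          + u [ (rho - r(x,t)) (1 - u) - kbar(x,t) ]

on a voxel grid, with no-flux (Neumann) closure at the brain boundary:
diffusivity is zero outside the brain mask so no flux crosses it, and the
density is pinned to zero in CSF and outside the brain, satisfying both
boundary statements (zero flux and zero boundary concentration) at once.

Anisotropic diffusion is discretized in conservation (flux) form with
face-averaged tensor components: axis fluxes from the diagonal entries,
cross-derivative contributions from the off-diagonal entries via
face-averaged central differences.  With all off-diagonals zero this is
exactly the standard 7-point variable-coefficient stencil, and the flux
form makes the scheme mass-conserving under the no-flux closure by
construction.  Time stepping is forward Euler with a CFL-type bound on dt
(the standard sufficient condition for explicit anisotropic diffusion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fields import CAVITY, CSF, GM, OUTSIDE, WM, DensityField, LabeledVolume, TensorField
from .therapy import (
    ChemotherapyPlan,
    RadiotherapyPlan,
    check_treatment_guard,
    chemo_rate,
    rt_rate,
    survival_fraction,
)
from .tissue import TissueParams, wm_proportion
from .viscoelastic import (
    DEFAULT_DHAT,
    DEFAULT_KAPPA,
    MaxwellWeichertModel,
    StressState,
    strain_proxy,
    stress_divergence_term,
    update_stress,
)

CFL_SAFETY = 0.9
CLIP_COUNT_TOL = 1e-12  # |overshoot| below this is floating-point noise, not clipping


@dataclass
class SimulationConfig:
    """Run-level knobs for :func:`simulate`.

    Times are days from simulation start.  ``dt=None`` selects the
    stability-bounded step automatically.  The feature flags switch off
    individual model components for ablations; ``u_detect`` is the imaging
    detection threshold used for output masks (0.4 by default).
    """

    t_end: float = 100.0
    dt: float | None = None
    u_detect: float = 0.4
    save_every: float = 10.0
    use_dti: bool = True
    use_viscoelastic: bool = True
    use_rt: bool = True
    use_chemo: bool = True
    kappa: float = DEFAULT_KAPPA
    dhat: float = DEFAULT_DHAT
    cavity_proliferation: bool = True
    cavity_diffusion: bool = True
    rt_mode: str = "rate"  # "rate": 1-S acts as a day^-1 loss; "instant": u <- S u
    stress_formulation: str = "normal_stress"  # or "gradient"

    def __post_init__(self):
        if not (0 < self.u_detect < 1):
            raise ValueError("u_detect must lie strictly in (0, 1)")
        if self.t_end < 0:
            raise ValueError("t_end must be non-negative")
        if self.rt_mode not in ("rate", "instant"):
            raise ValueError("rt_mode must be 'rate' or 'instant'")
        if self.stress_formulation not in ("normal_stress", "gradient"):
            raise ValueError("stress_formulation must be 'normal_stress' or 'gradient'")


@dataclass
class StepDiagnostics:
    time: float
    total_mass: float
    max_u: float
    dt: float
    clip_events: int


@dataclass
class SimulationResult:
    """Snapshots, final detection mask and per-step diagnostics."""

    snapshots: list[DensityField]
    final_mask: np.ndarray
    diagnostics: list[StepDiagnostics]
    config: SimulationConfig

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def final(self) -> DensityField:
        return self.snapshots[-1]

    def clip_events_after(self, step: int) -> int:
        return int(sum(d.clip_events for d in self.diagnostics[step:]))


def stable_dt(
    d_field: TensorField | np.ndarray,
    spacing,
    cadence: float = 1.0,
    safety: float = CFL_SAFETY,
) -> float:
    """Stability-bounded explicit time step (days).

    ``dt <= safety / (sum_axis 2 * D_max / h_axis^2)`` with ``D_max`` the
    largest tensor eigenvalue over the grid (or the largest scalar value).
    With zero diffusivity everywhere the bound is vacuous and the output
    cadence is returned instead.
    """
    if isinstance(d_field, TensorField):
        dmax = float(d_field.max_eigenvalue().max(initial=0.0))
    else:
        dmax = float(np.max(d_field, initial=0.0))
    if dmax <= 0:
        return float(cadence)
    denom = sum(2.0 * dmax / float(h) ** 2 for h in spacing)
    return safety / denom


def _masked_central_gradient(
    u: np.ndarray, axis: int, h: float, mask: np.ndarray
) -> np.ndarray:
    """Central difference with reflective (Neumann) ghosts at the mask edge.

    Neighbors outside ``mask`` (or the grid) are replaced by the center
    value, so no spurious cross-flux is generated where the density jumps
    to zero across the brain boundary.
    """
    if u.shape[axis] < 2:
        return np.zeros_like(u)
    up = np.empty_like(u)
    dn = np.empty_like(u)
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    first = [slice(None)] * 3
    last = [slice(None)] * 3
    first[axis] = slice(0, 1)
    last[axis] = slice(-1, None)
    lo, hi, first, last = tuple(lo), tuple(hi), tuple(first), tuple(last)

    up[lo] = np.where(mask[hi], u[hi], u[lo])
    up[last] = u[last]
    dn[hi] = np.where(mask[lo], u[lo], u[hi])
    dn[first] = u[first]
    return (up - dn) / (2.0 * h)


def weickert_divergence(
    u: np.ndarray,
    dbar: TensorField,
    spacing,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Discrete ``div(Dbar grad u)`` in conservation form.

    Per axis ``a`` the face flux is ``D_aa_face * d_a u + sum_{b != a}
    D_ab_face * d_b u_face`` with face values arithmetic means of the two
    adjacent voxels; the divergence telescopes the face fluxes, so total
    mass is conserved exactly when no flux crosses the ``mask`` boundary
    (faces with a non-diffusible side are closed).  With a diagonal tensor
    this reduces to the standard 7-point variable-coefficient stencil.
    """
    u = np.asarray(u, dtype=float)
    if mask is None:
        mask = np.ones(u.shape, dtype=bool)

    # central differences per axis, reused by the cross terms
    grads = [
        _masked_central_gradient(u, axis, float(spacing[axis]), mask)
        for axis in range(3)
    ]
    out = np.zeros_like(u)
    for a in range(3):
        h = float(spacing[a])
        if u.shape[a] < 2:
            continue
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)

        daa = dbar.component(a, a)
        flux = 0.5 * (daa[lo] + daa[hi]) * (u[hi] - u[lo]) / h
        for b in range(3):
            if b == a or u.shape[b] < 2:
                continue
            dab = dbar.component(a, b)
            gb_face = 0.5 * (grads[b][lo] + grads[b][hi])
            flux = flux + 0.5 * (dab[lo] + dab[hi]) * gb_face
        face_open = mask[lo] & mask[hi]
        flux[~face_open] = 0.0
        out[lo] += flux / h
        out[hi] -= flux / h
    return out


def step(
    u: np.ndarray,
    dt: float,
    diffusion_term: np.ndarray,
    stress_term: np.ndarray | float,
    rho_field: np.ndarray,
    r_field: np.ndarray,
    kbar_field: np.ndarray,
    zero_mask: np.ndarray,
) -> tuple[np.ndarray, int]:
    """One forward-Euler update of the density field.

    ``u' = clip(u + dt * [diffusion + stress + u ((rho - r)(1 - u) - kbar)], 0, 1)``
    with ``u'`` forced to zero on ``zero_mask`` (CSF and outside-brain).
    Returns the new field and the number of genuine clipping events
    (overshoots beyond floating-point noise).  NaN/Inf aborts the run.
    """
    reaction = u * ((rho_field - r_field) * (1.0 - u) - kbar_field)
    u_new = u + dt * (diffusion_term + stress_term + reaction)
    if not np.all(np.isfinite(u_new)):
        raise FloatingPointError(
            "non-finite density encountered; dt likely exceeds the stability bound"
        )
    over = u_new > 1.0 + CLIP_COUNT_TOL
    under = u_new < -CLIP_COUNT_TOL
    clip_events = int(over.sum() + under.sum())
    np.clip(u_new, 0.0, 1.0, out=u_new)
    u_new[zero_mask] = 0.0
    return u_new, clip_events


def extract_mask(u: np.ndarray | DensityField, threshold: float) -> np.ndarray:
    """Detection mask: voxels with density at or above the threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly in (0, 1)")
    arr = u.u if isinstance(u, DensityField) else np.asarray(u)
    return arr >= threshold


def _effective_tensor(
    dbar: TensorField, vol: LabeledVolume, params: TissueParams, config: SimulationConfig
) -> TensorField:
    """Apply the cavity policy: tumor may diffuse into the cavity with GM
    diffusivity (therapy never acts there); disabled via config."""
    if not config.cavity_diffusion:
        return dbar
    cav = vol.labels == CAVITY
    if not cav.any():
        return dbar
    comps = dbar.components.copy()
    comps[cav] = 0.0
    for idx in (0, 3, 5):  # xx, yy, zz
        comps[..., idx][cav] = params.d_gm_mm2
    return TensorField(comps, dbar.spacing)


def simulate(
    init: DensityField,
    vol: LabeledVolume,
    dbar: TensorField | np.ndarray,
    params: TissueParams,
    config: SimulationConfig,
    rt_plan: RadiotherapyPlan | None = None,
    chemo_plan: ChemotherapyPlan | None = None,
    mw_model: MaxwellWeichertModel | None = None,
) -> SimulationResult:
    """Integrate the growth PDE over ``[0, t_end]``.

    ``dbar`` may be a tensor field (DTI-guided) or a scalar diffusivity map
    (isotropic variant); a scalar map is promoted to ``D(x) * I`` and both
    paths share the same stencil.  Therapy calendars are honored day by
    day; the radiotherapy/chemotherapy rates are refreshed whenever the
    integer day index changes.  The run is fully deterministic.
    """
    if isinstance(dbar, np.ndarray) and dbar.ndim == 3:
        dbar = TensorField.isotropic(dbar, init.spacing)
    if dbar.shape != vol.shape or init.shape != vol.shape:
        raise ValueError("density, labels and diffusion fields must share a shape")
    dbar = _effective_tensor(dbar, vol, params, config)

    dt = config.dt if config.dt is not None else stable_dt(
        dbar, vol.spacing, cadence=min(config.save_every, 1.0)
    )
    bound = stable_dt(dbar, vol.spacing, cadence=float("inf"))
    if dt > bound * (1 + 1e-9):
        warnings.warn(
            f"dt={dt:.4g} exceeds the stability bound {bound:.4g}", stacklevel=2
        )

    # masks and static fields
    diffusible = vol.mask(GM, WM) | (
        vol.mask(CAVITY) if config.cavity_diffusion else np.zeros(vol.shape, bool)
    )
    zero_mask = vol.mask(OUTSIDE, CSF)
    rho_field = np.zeros(vol.shape)
    rho_field[vol.mask(GM, WM)] = params.rho
    if config.cavity_proliferation:
        rho_field[vol.mask(CAVITY)] = params.rho

    use_rt = config.use_rt and rt_plan is not None
    use_chemo = config.use_chemo and chemo_plan is not None
    omega = wm_proportion(vol) if use_chemo else np.zeros(vol.shape)

    use_stress = config.use_viscoelastic and config.kappa != 0 and config.dhat != 0
    if use_stress:
        model = mw_model or MaxwellWeichertModel()
        if config.stress_formulation == "normal_stress":
            stress_state = StressState(model, vol.shape)
        else:
            stress_state = StressState(model, (3,) + tuple(vol.shape))
        g_prev = _stress_operand(init.u, vol.spacing, config)

    u = init.u.copy()
    u[zero_mask] = 0.0
    t = 0.0
    voxel_volume = float(np.prod(vol.spacing))

    snapshots = [DensityField(u.copy(), vol.spacing, time=0.0)]
    diagnostics: list[StepDiagnostics] = []
    next_save = config.save_every
    guard_checked = False
    current_day = -1
    r_field = np.zeros(vol.shape)
    kbar_field = np.zeros(vol.shape)
    rt_instant_pending = False

    n_steps = max(0, int(math.ceil(config.t_end / dt - 1e-12)))
    for i in range(n_steps):
        dt_i = min(dt, config.t_end - t)
        day = int(math.floor(t))
        if day != current_day:
            current_day = day
            if use_rt and config.rt_mode == "rate":
                r_field = rt_rate(t, rt_plan, vol)
            elif use_rt:
                rt_instant_pending = rt_plan.dose_on_day(day) > 0
            if use_chemo:
                kbar_field = chemo_rate(t, chemo_plan, vol, omega)
            if not guard_checked and (r_field.any() or kbar_field.any()):
                check_treatment_guard(params.rho, r_field, kbar_field)
                guard_checked = True

        if use_rt and config.rt_mode == "instant" and rt_instant_pending:
            dose = rt_plan.dose_on_day(day)
            s = survival_fraction(rt_plan.alpha, rt_plan.beta, dose)
            target = vol.brain_mask & (vol.labels != CAVITY)
            u[target] *= s
            rt_instant_pending = False

        diffusion = weickert_divergence(u, dbar, vol.spacing, mask=diffusible)

        if use_stress:
            g_now = _stress_operand(u, vol.spacing, config)
            stress_state = update_stress(stress_state, g_now, g_prev, dt_i)
            g_prev = g_now
            stress_term = _stress_term(stress_state, g_now, vol, config)
        else:
            stress_term = 0.0

        u, clip_events = step(
            u, dt_i, diffusion, stress_term, rho_field, r_field, kbar_field, zero_mask
        )
        t += dt_i
        diagnostics.append(
            StepDiagnostics(
                time=t,
                total_mass=float(u.sum() * voxel_volume),
                max_u=float(u.max()),
                dt=dt_i,
                clip_events=clip_events,
            )
        )
        if t >= next_save - 1e-9 or i == n_steps - 1:
            snapshots.append(DensityField(u.copy(), vol.spacing, time=t))
            while next_save <= t + 1e-9:
                next_save += config.save_every

    return SimulationResult(
        snapshots=snapshots,
        final_mask=extract_mask(u, config.u_detect),
        diagnostics=diagnostics,
        config=config,
    )


def _stress_operand(u: np.ndarray, spacing, config: SimulationConfig):
    """The field whose history drives the hereditary integral."""
    eps = strain_proxy(u, config.kappa)
    if config.stress_formulation == "normal_stress":
        return eps
    return np.stack(
        [np.gradient(eps, float(spacing[a]), axis=a) for a in range(3)], axis=0
    )


def _stress_term(
    state: StressState, g_now, vol: LabeledVolume, config: SimulationConfig
) -> np.ndarray:
    """div(Dhat grad sigma) for the scalar formulation, or the matching
    div(Dhat theta2)-style contraction when the operand is grad(eps)."""
    mask = vol.brain_mask
    if config.stress_formulation == "normal_stress":
        sigma = state.sigma(g_now)
        return stress_divergence_term(sigma, config.dhat, vol.spacing, mask=mask)
    theta2 = state.sigma(g_now)  # one hereditary response per gradient component
    out = np.zeros(vol.shape)
    for a in range(3):
        h = float(vol.spacing[a])
        grad_a = np.gradient(config.dhat * theta2[a], h, axis=a)
        grad_a[~mask] = 0.0
        out += grad_a
    return out
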