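"""PDE solver: stability bound, anisotropic stencil, stepping, simulate."""

import warnings

import numpy as np
import pytest

import gliosim as g
from gliosim.fields import CSF, GM, OUTSIDE, WM, TensorField

from conftest import uniform_volume


def reference_rd_step(u, d_scalar, mask, spacing, dt, rho):
    """Independently coded plain reaction-diffusion step (7-point stencil).

    Face diffusivity is the arithmetic mean of the two voxels, flux across
    the mask boundary is closed; logistic reaction; forward Euler; clip.
    Written with explicit per-axis padding rather than the solver's
    face-flux loop.
    """
    div = np.zeros_like(u)
    for axis in range(3):
        h2 = float(spacing[axis]) ** 2
        u_up = np.roll(u, -1, axis=axis)
        u_dn = np.roll(u, 1, axis=axis)
        d_up = 0.5 * (d_scalar + np.roll(d_scalar, -1, axis=axis))
        d_dn = 0.5 * (d_scalar + np.roll(d_scalar, 1, axis=axis))
        open_up = mask & np.roll(mask, -1, axis=axis)
        open_dn = mask & np.roll(mask, 1, axis=axis)
        # kill the wrap-around faces at the grid edges
        edge_lo = [slice(None)] * 3
        edge_hi = [slice(None)] * 3
        edge_lo[axis] = slice(0, 1)
        edge_hi[axis] = slice(-1, None)
        open_dn[tuple(edge_lo)] = False
        open_up[tuple(edge_hi)] = False
        div += np.where(open_up, d_up * (u_up - u), 0.0) / h2
        div += np.where(open_dn, d_dn * (u_dn - u), 0.0) / h2
    u_new = u + dt * (div + rho * u * (1.0 - u))
    u_new = np.clip(u_new, 0.0, 1.0)
    u_new[~mask] = 0.0
    return u_new


class TestStableDt:
    def test_zero_diffusivity_falls_back_to_cadence(self):
        d = np.zeros((4, 4, 4))
        assert g.stable_dt(d, (1, 1, 1), cadence=2.5) == 2.5

    def test_isotropic_bound_matches_h2_over_6d(self):
        d = np.full((4, 4, 4), 0.2)
        dt = g.stable_dt(d, (1.0, 1.0, 1.0))
        assert dt == pytest.approx(0.9 * 1.0 / (6 * 0.2))

    def test_doubling_spacing_quadruples_bound(self):
        d = np.full((4, 4, 4), 0.2)
        assert g.stable_dt(d, (2.0, 2.0, 2.0)) == pytest.approx(
            4 * g.stable_dt(d, (1.0, 1.0, 1.0))
        )

    def test_tensor_field_uses_largest_eigenvalue(self, small_dbar, small_volume):
        dt = g.stable_dt(small_dbar, small_volume.spacing)
        dmax = small_dbar.max_eigenvalue().max()
        assert dt == pytest.approx(0.9 / (6 * dmax))


class TestWeickertDivergence:
    def test_constant_field_gives_zero(self, small_dbar):
        u = np.full(small_dbar.shape, 0.7)
        out = g.weickert_divergence(u, small_dbar, (1, 1, 1))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_1d_quadratic_with_uniform_d(self):
        # u = x^2, diagonal D = d*I -> interior value 2d
        n = 8
        u = np.zeros((n, 1, 1))
        u[:, 0, 0] = np.arange(n, dtype=float) ** 2
        d = 0.3
        tensor = TensorField.isotropic(np.full((n, 1, 1), d), (1.0, 1.0, 1.0))
        out = g.weickert_divergence(u, tensor, (1.0, 1.0, 1.0))
        assert np.allclose(out[1:-1, 0, 0], 2 * d)

    def test_reduces_to_seven_point_stencil_for_diagonal_tensor(self):
        rng = np.random.default_rng(5)
        shape = (10, 10, 10)
        u = rng.random(shape)
        d = rng.random(shape) * 0.5
        mask = rng.random(shape) > 0.2
        u[~mask] = 0.0
        tensor = TensorField.isotropic(d, (1.0, 1.2, 0.8))
        ours = g.weickert_divergence(u, tensor, (1.0, 1.2, 0.8), mask=mask)
        ref = np.zeros(shape)
        # reference: independent per-axis flux differencing
        for axis, h in enumerate((1.0, 1.2, 0.8)):
            for idx in np.ndindex(shape):
                if not mask[idx]:
                    continue
                for sgn in (+1, -1):
                    nbr = list(idx)
                    nbr[axis] += sgn
                    if not (0 <= nbr[axis] < shape[axis]):
                        continue
                    nbr = tuple(nbr)
                    if not mask[nbr]:
                        continue
                    ref[idx] += 0.5 * (d[idx] + d[nbr]) * (u[nbr] - u[idx]) / h**2
        assert np.allclose(ours, ref, atol=1e-12)

    def test_axis_permutation_symmetry(self, small_volume, small_dbar):
        # permuting grid axes and tensor components permutes the output
        rng = np.random.default_rng(11)
        u = rng.random(small_volume.shape) * small_volume.brain_mask
        mask = small_volume.mask(GM, WM)
        out = g.weickert_divergence(u, small_dbar, small_volume.spacing, mask=mask)

        perm = (1, 2, 0)
        p_mats = np.transpose(small_dbar.as_matrices(), perm + (3, 4))
        p_mats = p_mats[..., perm, :][..., :, perm]
        p_tensor = TensorField.from_matrices(p_mats, small_volume.spacing)
        p_out = g.weickert_divergence(
            np.transpose(u, perm), p_tensor, small_volume.spacing,
            mask=np.transpose(mask, perm),
        )
        assert np.allclose(p_out, np.transpose(out, perm), atol=1e-12)

    def test_axis_flip_symmetry(self, small_volume, small_dbar):
        # mirroring the x axis flips the sign of the xy/xz components
        rng = np.random.default_rng(12)
        u = rng.random(small_volume.shape) * small_volume.brain_mask
        mask = small_volume.mask(GM, WM)
        out = g.weickert_divergence(u, small_dbar, small_volume.spacing, mask=mask)

        f_mats = small_dbar.as_matrices()[::-1].copy()
        flip = np.diag([-1.0, 1.0, 1.0])
        f_mats = flip @ f_mats @ flip
        f_tensor = TensorField.from_matrices(f_mats, small_volume.spacing)
        f_out = g.weickert_divergence(
            u[::-1], f_tensor, small_volume.spacing, mask=mask[::-1]
        )
        assert np.allclose(f_out, out[::-1], atol=1e-12)


class TestStep:
    def test_zero_density_is_fixed_point(self):
        u = np.zeros((4, 4, 4))
        out, clips = g.step(
            u, 0.1, np.zeros_like(u), 0.0, np.full_like(u, 0.012),
            np.zeros_like(u), np.zeros_like(u), np.zeros_like(u, dtype=bool),
        )
        assert not out.any() and clips == 0

    def test_capacity_is_logistic_fixed_point(self):
        u = np.ones((2, 2, 2))
        out, _ = g.step(
            u, 0.1, np.zeros_like(u), 0.0, np.full_like(u, 0.012),
            np.zeros_like(u), np.zeros_like(u), np.zeros_like(u, dtype=bool),
        )
        assert np.all(out == 1.0)

    def test_nan_detection_aborts(self):
        u = np.zeros((2, 2, 2))
        bad = np.full_like(u, np.nan)
        with pytest.raises(FloatingPointError):
            g.step(u, 0.1, bad, 0.0, u, u, u, np.zeros_like(u, dtype=bool))

    def test_0d_logistic_matches_closed_form(self):
        # diffusion-free logistic from u0=0.1, rho=0.012/day, dt=0.1:
        # u(t) = 1 / (1 + 9 exp(-rho t)) within 1e-3 at t=100
        rho, dt, u0, t_end = 0.012, 0.1, 0.1, 100.0
        u = np.full((1, 1, 1), u0)
        zeros = np.zeros_like(u)
        zmask = np.zeros_like(u, dtype=bool)
        for _ in range(int(round(t_end / dt))):
            u, _ = g.step(u, dt, zeros, 0.0, np.full_like(u, rho), zeros, zeros, zmask)
        exact = 1.0 / (1.0 + 9.0 * np.exp(-rho * t_end))
        assert abs(u[0, 0, 0] - exact) < 1e-3


class TestExtractMask:
    def test_threshold_semantics(self):
        u = np.full((3, 3, 3), 0.39)
        assert not g.extract_mask(u, 0.4).any()
        u[1, 1, 1] = 1.0
        assert g.extract_mask(u, 0.4)[1, 1, 1]

    def test_threshold_nesting(self):
        rng = np.random.default_rng(2)
        u = rng.random((8, 8, 8))
        hi, lo = g.extract_mask(u, 0.5), g.extract_mask(u, 0.3)
        assert np.all(~hi | lo)  # mask(0.5) subset of mask(0.3)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            g.extract_mask(np.zeros((2, 2, 2)), 1.5)


class TestSimulate:
    def test_t_end_zero_returns_init_only(self, small_volume, small_dbar, tissue_params):
        init = g.seed_tumor(small_volume, (8, 12, 12), 1.0)
        cfg = g.SimulationConfig(t_end=0.0)
        res = g.simulate(init, small_volume, small_dbar, tissue_params, cfg)
        assert len(res.snapshots) == 1
        assert np.array_equal(res.snapshots[0].u, init.u)

    def test_pure_diffusion_conserves_mass(self, small_volume, small_dbar):
        params = g.TissueParams(rho=0.0)
        init = g.seed_tumor(small_volume, (8, 12, 12), 2.0)
        dt = g.stable_dt(small_dbar, small_volume.spacing)
        cfg = g.SimulationConfig(t_end=120 * dt, dt=dt, save_every=1e9,
                                 use_rt=False, use_chemo=False, use_viscoelastic=False)
        res = g.simulate(init, small_volume, small_dbar, params, cfg)
        masses = np.array([d.total_mass for d in res.diagnostics])
        assert len(masses) >= 100
        m0 = init.total_mass()
        assert np.all(np.abs(masses - m0) <= 1e-6 * m0)

    def test_csf_and_outside_stay_zero(self, small_volume, small_dbar, tissue_params):
        init = g.seed_tumor(small_volume, (8, 12, 12), 2.0)
        cfg = g.SimulationConfig(t_end=30.0, save_every=10.0)
        res = g.simulate(init, small_volume, small_dbar, tissue_params, cfg)
        forbidden = small_volume.mask(CSF, OUTSIDE)
        for snap in res.snapshots:
            assert not snap.u[forbidden].any()

    def test_matches_independent_plain_rd_reference(self, tissue_params):
        # Swanson-style reduction: r=0, kbar=0, kappa=0, scalar D(x)
        spec = g.default_spec(shape=(16, 16, 16), with_cavity=False, seed=1)
        vol = g.make_brain_phantom(spec)
        d_scalar = g.scalar_diffusion_map(vol, tissue_params)
        init = g.seed_tumor(vol, (8, 8, 8), 1.5)
        dt = g.stable_dt(d_scalar, vol.spacing)
        n_steps = 60
        cfg = g.SimulationConfig(
            t_end=n_steps * dt, dt=dt, save_every=1e9,
            use_rt=False, use_chemo=False, use_viscoelastic=False,
            cavity_diffusion=False, cavity_proliferation=False,
        )
        res = g.simulate(init, vol, d_scalar, tissue_params, cfg)

        mask = vol.mask(GM, WM)
        u_ref = init.u.copy()
        u_ref[~mask] = 0.0
        rho_field = np.where(mask, tissue_params.rho, 0.0)
        for _ in range(n_steps):
            u_ref = reference_rd_step(u_ref, d_scalar, mask, vol.spacing, dt, rho_field)
        assert np.max(np.abs(res.final.u - u_ref)) <= 1e-10

    def test_isotropic_tensor_equals_scalar_path(self, tissue_params):
        spec = g.default_spec(shape=(16, 16, 16), with_cavity=False, seed=2)
        vol = g.make_brain_phantom(spec)
        d_scalar = g.scalar_diffusion_map(vol, tissue_params)
        tensor = TensorField.isotropic(d_scalar, vol.spacing)
        init = g.seed_tumor(vol, (8, 8, 8), 1.5)
        cfg = g.SimulationConfig(t_end=10.0, save_every=1e9,
                                 use_rt=False, use_chemo=False, use_viscoelastic=False)
        res_s = g.simulate(init, vol, d_scalar, tissue_params, cfg)
        res_t = g.simulate(init, vol, tensor, tissue_params, cfg)
        assert np.array_equal(res_s.final.u, res_t.final.u)

    def test_disabling_viscoelasticity_is_bitwise_neutral(self, small_volume, small_dbar, tissue_params):
        init = g.seed_tumor(small_volume, (8, 12, 12), 1.5)
        base = dict(t_end=15.0, save_every=1e9, use_rt=False, use_chemo=False)
        res_off = g.simulate(init, small_volume, small_dbar, tissue_params,
                             g.SimulationConfig(use_viscoelastic=False, **base))
        res_kappa0 = g.simulate(init, small_volume, small_dbar, tissue_params,
                                g.SimulationConfig(use_viscoelastic=True, kappa=0.0, **base))
        assert np.array_equal(res_off.final.u, res_kappa0.final.u)

    def test_therapy_run_pointwise_below_untreated(self, small_volume, small_dbar, tissue_params):
        init = g.seed_tumor(small_volume, (8, 12, 12), 2.0)
        rt = g.make_therapy_calendar("radiotherapy", start_day=0)
        chemo = g.make_therapy_calendar("chemotherapy", start_day=0)
        base = dict(t_end=40.0, save_every=10.0, use_viscoelastic=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            treated = g.simulate(init, small_volume, small_dbar, tissue_params,
                                 g.SimulationConfig(**base), rt_plan=rt, chemo_plan=chemo)
        untreated = g.simulate(init, small_volume, small_dbar, tissue_params,
                               g.SimulationConfig(use_rt=False, use_chemo=False, **base))
        assert len(treated.snapshots) == len(untreated.snapshots)
        for s_t, s_u in zip(treated.snapshots, untreated.snapshots):
            assert np.all(s_t.u <= s_u.u + 1e-12)

    def test_deterministic_rerun(self, small_volume, small_dbar, tissue_params):
        init = g.seed_tumor(small_volume, (8, 12, 12), 1.0)
        cfg = g.SimulationConfig(t_end=10.0, save_every=5.0)
        a = g.simulate(init, small_volume, small_dbar, tissue_params, cfg)
        b = g.simulate(init, small_volume, small_dbar, tissue_params, cfg)
        assert np.array_equal(a.final.u, b.final.u)
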