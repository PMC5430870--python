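"""Maxwell-Weichert viscoelasticity and the stress-diffusion term.

Brain tissue is modeled as a generalized Maxwell (Maxwell-Weichert) solid:
``n`` spring-dashpot elements in parallel with a free spring.  Its
relaxation modulus is the Prony series

    E(t) = sum_k E_k exp(-t / tau_k) + E_inf,      tau_k = eta_k / E_k.

Stress follows from strain history through the Boltzmann hereditary
integral

    sigma(t) = (sum_k E_k) g(t)
             + int_0^t sum_k (E_k / tau_k) exp(-(t - s)/tau_k) g(s) ds,

where the operand ``g`` is the strain-derived field (the volumetric strain
proxy ``eps = kappa * u`` in the scalar normal-stress formulation, or the
components of ``grad eps`` in the gradient formulation; for spatially
uniform moduli the two commute with the spatial derivatives and produce
the same stress-diffusion term).  The integral is advanced with one
recursive exponential accumulator per element, exact for piecewise-linear
strain, so memory cost is independent of history length.

The stress feeds back on the density through ``div(Dhat grad sigma)`` with
``Dhat`` a diagonal tensor with negative entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SECONDS_PER_DAY = 86400.0

DEFAULT_E1_PA = 3156.0
DEFAULT_E_INF_PA = DEFAULT_E1_PA / 6.0  # free spring: E1 = 6 E_inf
DEFAULT_ETA1_PA_S = 8.9e-8
DEFAULT_DHAT = -1e-14  # stress diffusion, cells/(Pa day)
DEFAULT_KAPPA = 0.01  # volumetric strain per unit normalized density


@dataclass
class MaxwellWeichertModel:
    """Spring/dashpot parameters of the generalized Maxwell solid.

    ``e_moduli`` (Pa) and ``viscosities`` (Pa*s) describe the n Maxwell
    elements; ``e_inf`` (Pa) the free spring.  Relaxation times ``tau_k``
    are exposed in days.  The defaults are the single-element brain-tissue
    values E1 = 3156 Pa, E_inf = E1/6, eta1 = 8.9e-8 Pa*s — note eta1/E1
    is ~3e-16 days, i.e. the element relaxes instantaneously on the day
    scale of tumor growth (a literal consequence of the source parameters,
    handled exactly by the recursion).
    """

    e_moduli: tuple[float, ...] = (DEFAULT_E1_PA,)
    viscosities: tuple[float, ...] = (DEFAULT_ETA1_PA_S,)
    e_inf: float = DEFAULT_E_INF_PA

    def __post_init__(self):
        self.e_moduli = tuple(float(e) for e in np.atleast_1d(self.e_moduli))
        self.viscosities = tuple(float(v) for v in np.atleast_1d(self.viscosities))
        if len(self.e_moduli) != len(self.viscosities) or not self.e_moduli:
            raise ValueError("need n >= 1 matching moduli/viscosity pairs")
        if any(e <= 0 for e in self.e_moduli) or any(v <= 0 for v in self.viscosities):
            raise ValueError("moduli and viscosities must be positive")
        if self.e_inf <= 0:
            raise ValueError("free-spring modulus must be positive")

    @property
    def n_elements(self) -> int:
        return len(self.e_moduli)

    @property
    def taus_days(self) -> np.ndarray:
        """Relaxation times eta_k / E_k, converted from seconds to days."""
        e = np.asarray(self.e_moduli)
        eta = np.asarray(self.viscosities)
        return eta / e / SECONDS_PER_DAY

    @property
    def instantaneous_modulus(self) -> float:
        """E(0) = sum E_k + E_inf, Pa."""
        return float(sum(self.e_moduli) + self.e_inf)


def relaxation_modulus(t, model: MaxwellWeichertModel):
    """Relaxation modulus ``E(t) = sum_k E_k exp(-t/tau_k) + E_inf`` (Pa).

    ``t`` is in days (scalar or array, non-negative).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    taus = model.taus_days
    e = np.asarray(model.e_moduli)
    out = model.e_inf + np.sum(
        e * np.exp(-t[..., None] / taus), axis=-1
    )
    return float(out) if out.ndim == 0 else out


def strain_proxy(u: np.ndarray, kappa: float) -> np.ndarray:
    """Volumetric strain proxy ``eps = kappa * u``.

    The growing tumor dilates the tissue in proportion to local density;
    ``kappa`` (unitless strain per unit normalized density) is the minimal
    coupling that turns the density field into a strain history.
    """
    return kappa * np.asarray(u, dtype=float)


@dataclass
class StressState:
    """Hereditary-integral state: one exponential accumulator per element.

    ``accumulators[k]`` carries the convolution
    ``int_0^t (E_k/tau_k) exp(-(t-s)/tau_k) g(s) ds`` for the operand field
    ``g`` and decays to zero when the strain is held at zero for times long
    against ``tau_k``.
    """

    model: MaxwellWeichertModel
    shape: tuple[int, ...]
    accumulators: np.ndarray = None  # shape (n_elements,) + field shape

    def __post_init__(self):
        if self.accumulators is None:
            self.accumulators = np.zeros((self.model.n_elements,) + tuple(self.shape))

    @property
    def sigma_offset(self) -> np.ndarray:
        """The convolution part of sigma (add ``sum(E_k) * g_now`` for sigma)."""
        return self.accumulators.sum(axis=0)

    def sigma(self, g_now: np.ndarray) -> np.ndarray:
        """Stress field for the current operand value ``g_now`` (Pa)."""
        return float(sum(self.model.e_moduli)) * np.asarray(g_now) + self.sigma_offset


def update_stress(
    state: StressState,
    g_now: np.ndarray,
    g_prev: np.ndarray,
    dt: float,
) -> StressState:
    """Advance the hereditary integral one step of length ``dt`` (days).

    The operand ``g`` is taken piecewise-linear from ``g_prev`` to
    ``g_now`` over the step; the per-element update

        a_k <- exp(-dt/tau_k) a_k
             + E_k [ (1 - E) g_prev + (1 - (1 - E)/lam) (g_now - g_prev) ],

    with ``lam = dt/tau_k`` and ``E = exp(-lam)``, is the exact integral of
    the exponential kernel against the linear segment, so the recursion
    matches direct quadrature up to the oracle's own error and stays exact
    even for relaxation times far below ``dt`` (where ``E`` underflows to 0
    and the element tracks ``g`` instantaneously).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g_now = np.asarray(g_now, dtype=float)
    g_prev = np.asarray(g_prev, dtype=float)
    taus = state.model.taus_days
    for k, (e_k, tau_k) in enumerate(zip(state.model.e_moduli, taus)):
        lam = dt / tau_k
        with np.errstate(under="ignore"):
            decay = np.exp(-lam)
        one_minus = -np.expm1(-lam)  # 1 - exp(-lam), accurate for small lam
        # integral weight for the linear ramp; lam -> 0 limit is lam/2
        if lam < 1e-8:
            ramp = lam / 2.0
        else:
            ramp = 1.0 - one_minus / lam
        state.accumulators[k] = decay * state.accumulators[k] + e_k * (
            one_minus * g_prev + ramp * (g_now - g_prev)
        )
    return state


def stress_divergence_term(
    sigma: np.ndarray,
    dhat: np.ndarray | float,
    spacing,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Stress-diffusion contribution ``div(Dhat grad sigma)`` (day^-1).

    ``dhat`` is the diagonal of the (negative) stress-diffusion tensor,
    either a scalar or per-axis values in cells/(Pa day).  Face fluxes are
    zeroed across the ``mask`` boundary (zero-flux closure at the brain
    surface); a uniform ``sigma`` or a zero ``dhat`` gives a zero term.
    """
    sigma = np.asarray(sigma, dtype=float)
    dvec = np.broadcast_to(np.asarray(dhat, dtype=float), (3,))
    if np.any(dvec > 0):
        raise ValueError("stress-diffusion entries must be <= 0")
    if mask is None:
        mask = np.ones(sigma.shape, dtype=bool)
    out = np.zeros_like(sigma)
    for axis in range(3):
        h = float(spacing[axis])
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        face_open = mask[lo] & mask[hi]
        flux = np.zeros_like(sigma[lo])
        np.subtract(sigma[hi], sigma[lo], out=flux)
        flux *= dvec[axis] / h
        flux[~face_open] = 0.0
        # divergence: +F/h at the cell below the face, -F/h at the cell above
        out[lo] += flux / h
        out[hi] -= flux / h
    return out
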