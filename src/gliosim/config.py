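"""YAML configuration with the standard low-grade-glioma parameter set.

An empty config yields the full default parameter table: D_GM = 0.0013
cm^2/day, D_WM = 5 D_GM, rho = 0.012/day, one Maxwell element with
E1 = 3156 Pa, E_inf = E1/6, eta1 = 8.9e-8 Pa*s, alpha = 0.027/Gy with
alpha/beta = 10 Gy, chemotherapy kill 0.0196/day, stress diffusion -1e-14,
detection threshold u = 0.4.  Unknown keys are rejected (typo guard) and
an inconsistent (alpha, beta, alpha_beta_ratio) triple is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import yaml

from .solver import SimulationConfig
from .therapy import DEFAULT_ALPHA_BETA_RATIO_GY, DEFAULT_ALPHA_PER_GY, DEFAULT_CHEMO_KILL_PER_DAY
from .tissue import DEFAULT_D_GM_CM2_PER_DAY, DEFAULT_RHO_PER_DAY, DEFAULT_WM_TO_GM_RATIO, TissueParams
from .viscoelastic import (
    DEFAULT_DHAT,
    DEFAULT_E1_PA,
    DEFAULT_ETA1_PA_S,
    DEFAULT_KAPPA,
    MaxwellWeichertModel,
)

logger = logging.getLogger(__name__)


@dataclass
class Parameters:
    """Flat view of every tunable model parameter with its default."""

    # tissue
    d_gm: float = DEFAULT_D_GM_CM2_PER_DAY  # cm^2/day
    d_wm: float = DEFAULT_D_GM_CM2_PER_DAY * DEFAULT_WM_TO_GM_RATIO  # cm^2/day
    rho: float = DEFAULT_RHO_PER_DAY  # day^-1
    # radiotherapy (LQ)
    alpha: float = DEFAULT_ALPHA_PER_GY  # Gy^-1
    beta: float | None = None  # Gy^-2; derived from alpha/ratio when absent
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO_GY  # Gy
    # chemotherapy
    k: float = DEFAULT_CHEMO_KILL_PER_DAY  # day^-1
    # viscoelasticity (n Maxwell elements)
    e_moduli: tuple[float, ...] = (DEFAULT_E1_PA,)  # Pa
    viscosities: tuple[float, ...] = (DEFAULT_ETA1_PA_S,)  # Pa*s
    e_inf: float = DEFAULT_E1_PA / 6.0  # Pa
    kappa: float = DEFAULT_KAPPA  # strain per unit density
    dhat: float = DEFAULT_DHAT  # cells/(Pa day)
    # simulation
    t_end: float = 100.0  # days
    dt: float | None = None  # days; None -> stability bound
    u_detect: float = 0.4
    save_every: float = 10.0
    use_dti: bool = True
    use_viscoelastic: bool = True
    use_rt: bool = True
    use_chemo: bool = True
    cavity_proliferation: bool = True
    cavity_diffusion: bool = True
    rt_mode: str = "rate"
    stress_formulation: str = "normal_stress"

    def __post_init__(self):
        if self.beta is None:
            self.beta = self.alpha / self.alpha_beta_ratio
        else:
            implied = self.alpha / self.alpha_beta_ratio
            if abs(self.beta - implied) > 1e-12 * max(1.0, abs(implied)):
                raise ValueError(
                    f"inconsistent LQ triple: alpha={self.alpha}, beta={self.beta}, "
                    f"alpha/beta={self.alpha_beta_ratio} implies beta={implied}"
                )
        # delegate range checks to the domain dataclasses
        self.tissue_params()
        self.maxwell_model()

    def tissue_params(self) -> TissueParams:
        return TissueParams(d_gm=self.d_gm, d_wm=self.d_wm, rho=self.rho)

    def maxwell_model(self) -> MaxwellWeichertModel:
        return MaxwellWeichertModel(
            e_moduli=self.e_moduli, viscosities=self.viscosities, e_inf=self.e_inf
        )

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            t_end=self.t_end,
            dt=self.dt,
            u_detect=self.u_detect,
            save_every=self.save_every,
            use_dti=self.use_dti,
            use_viscoelastic=self.use_viscoelastic,
            use_rt=self.use_rt,
            use_chemo=self.use_chemo,
            kappa=self.kappa,
            dhat=self.dhat,
            cavity_proliferation=self.cavity_proliferation,
            cavity_diffusion=self.cavity_diffusion,
            rt_mode=self.rt_mode,
            stress_formulation=self.stress_formulation,
        )


def load_config(path) -> Parameters:
    """Load a YAML config; absent keys keep their defaults, overrides are logged."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dc_fields(Parameters)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        logger.info("config override: %s = %r", key, value)
    for key in ("e_moduli", "viscosities"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return Parameters(**raw)
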