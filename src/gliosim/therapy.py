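"""Radiotherapy and chemotherapy loss terms.

Radiotherapy uses the linear-quadratic (LQ) cell-survival model: a fraction
of dose ``d`` leaves a surviving fraction ``S = exp(-alpha*d - beta*d^2)``,
and on a fraction day the per-day kill rate is ``r = 1 - S``, applied to
the density through the logistic-shaped loss ``R(u) = r * u * (1 - u)``.

Chemotherapy is a first-order kill ``C(u) = kbar * u`` whose rate depends
on tissue: the nominal rate ``k`` in gray matter, and ``k / (k + omega)``
in white matter, where ``omega`` is the local white-matter proportion —
tissue heterogeneity modulates drug absorption.

Neither therapy acts in the resection cavity or outside the brain.  Both
rates are zero on days with no scheduled treatment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fields import CAVITY, GM, WM, LabeledVolume

DEFAULT_ALPHA_PER_GY = 0.027
DEFAULT_ALPHA_BETA_RATIO_GY = 10.0
DEFAULT_CHEMO_KILL_PER_DAY = 0.0196


@dataclass
class RadiotherapyPlan:
    """Fractionation calendar with LQ coefficients.

    ``fraction_days`` are integer day indices from simulation start;
    ``doses`` are the per-fraction doses in Gy.  ``beta`` defaults to
    ``alpha / 10`` (the conventional alpha/beta = 10 Gy tumor ratio).
    ``dose_weight`` is an optional per-voxel multiplicative dose map
    (uniform over the brain when None).
    """

    fraction_days: list[int]
    doses: list[float]
    alpha: float = DEFAULT_ALPHA_PER_GY
    beta: float | None = None
    dose_weight: np.ndarray | None = None

    def __post_init__(self):
        if len(self.fraction_days) != len(self.doses):
            raise ValueError("fraction_days and doses must have equal length")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.beta is None:
            self.beta = self.alpha / DEFAULT_ALPHA_BETA_RATIO_GY
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        self._dose_by_day = {}
        for day, dose in zip(self.fraction_days, self.doses):
            self._dose_by_day[int(day)] = self._dose_by_day.get(int(day), 0.0) + dose

    @property
    def total_dose(self) -> float:
        return float(sum(self.doses))

    def dose_on_day(self, day: int) -> float:
        return self._dose_by_day.get(int(day), 0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fractions": [
                    {"day": int(d), "dose": float(x)}
                    for d, x in zip(self.fraction_days, self.doses)
                ],
                "alpha": self.alpha,
                "beta": self.beta,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RadiotherapyPlan":
        obj = json.loads(text)
        return cls(
            fraction_days=[f["day"] for f in obj["fractions"]],
            doses=[f["dose"] for f in obj["fractions"]],
            alpha=obj.get("alpha", DEFAULT_ALPHA_PER_GY),
            beta=obj.get("beta"),
        )


@dataclass
class ChemotherapyPlan:
    """Active-day calendar with the nominal kill rate ``k`` (day^-1)."""

    active_days: list[int]
    k: float = DEFAULT_CHEMO_KILL_PER_DAY

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("kill rate k must be non-negative")
        self._active = frozenset(int(d) for d in self.active_days)

    def is_active(self, day: int) -> bool:
        return int(day) in self._active

    @property
    def n_active_days(self) -> int:
        return len(self._active)

    def to_json(self) -> str:
        return json.dumps(
            {"active_days": sorted(self._active), "k": self.k}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "ChemotherapyPlan":
        obj = json.loads(text)
        return cls(active_days=obj["active_days"], k=obj.get("k", DEFAULT_CHEMO_KILL_PER_DAY))


def survival_fraction(alpha: float, beta: float, dose) -> np.ndarray | float:
    """LQ surviving fraction ``S = exp(-alpha*d - beta*d^2)``."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    s = np.exp(-alpha * dose - beta * dose**2)
    return float(s) if s.ndim == 0 else s


def rt_rate(t: float, plan: RadiotherapyPlan | None, vol: LabeledVolume) -> np.ndarray:
    """Per-voxel radiotherapy kill rate ``r(x, t)`` (day^-1).

    Zero on non-fraction days; on a fraction day, ``1 - S`` over the brain
    except the resection cavity, which receives no therapy effect.
    """
    r = np.zeros(vol.shape, dtype=float)
    if plan is None:
        return r
    dose = plan.dose_on_day(int(np.floor(t)))
    if dose <= 0:
        return r
    target = vol.brain_mask & (vol.labels != CAVITY)
    if plan.dose_weight is not None:
        voxel_dose = np.where(target, dose * plan.dose_weight, 0.0)
        r[target] = 1.0 - survival_fraction(plan.alpha, plan.beta, voxel_dose[target])
    else:
        r[target] = 1.0 - survival_fraction(plan.alpha, plan.beta, dose)
    return r


def radiotherapy_loss(u: np.ndarray, r_field: np.ndarray) -> np.ndarray:
    """Loss term ``R(u) = r * u * (1 - u)`` (vanishes at u = 0 and u = 1)."""
    return r_field * u * (1.0 - u)


def chemo_rate(
    t: float,
    plan: ChemotherapyPlan | None,
    vol: LabeledVolume,
    omega: np.ndarray,
) -> np.ndarray:
    """Per-voxel chemotherapy kill rate ``kbar(x, t)`` (day^-1).

    On active days: ``k`` in GM, ``k / (k + omega)`` in WM with ``omega``
    the local WM proportion; zero in CSF, cavity and outside the brain,
    and zero everywhere on inactive days.
    """
    kbar = np.zeros(vol.shape, dtype=float)
    if plan is None or not plan.is_active(int(np.floor(t))):
        return kbar
    k = plan.k
    gm = vol.labels == GM
    wm = vol.labels == WM
    kbar[gm] = k
    kbar[wm] = k / (k + omega[wm])
    return kbar


def chemotherapy_loss(u: np.ndarray, kbar_field: np.ndarray) -> np.ndarray:
    """Loss term ``C(u) = kbar * u``."""
    return kbar_field * u


def check_treatment_guard(
    rho: float, r_field: np.ndarray, kbar_field: np.ndarray
) -> bool:
    """Warn when the combined treatment rate reaches the proliferation rate.

    The growth model assumes treatment is weaker than proliferation (the
    gross tumor volume keeps increasing under therapy).  Returns True when
    the assumption holds everywhere, False (with a warning) otherwise.
    """
    worst = float(np.max(r_field + kbar_field, initial=0.0))
    if worst >= rho:
        warnings.warn(
            f"treatment rate {worst:.4g}/day >= proliferation rate {rho:.4g}/day: "
            "the treatment-weaker-than-proliferation assumption is violated",
            stacklevel=2,
        )
        return False
    return True
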