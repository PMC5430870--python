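"""Segmentation-overlap metrics and the ablation harness.

Simulated growth is scored against a reference mask with the Jaccard score
``JS = |S & GT| / |S | GT|`` and the Dice coefficient
``DC = 2 |S & GT| / (|S| + |GT|)``; the two are tied by
``DC = 2 JS / (1 + JS)``.  The ablation harness re-runs a scenario with
individual model components switched off (treatments, DTI guidance,
viscoelasticity) and reports the metric decrease of each variant against
the full-model run, mirroring the treatment/DTI/viscoelasticity ablation
design used to study the model's components.  Since no clinical ground
truth ships with the package, the full-model simulation serves as the
reference, so the deltas are self-consistency measures of component
influence, not clinical accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phantom import PhantomSpec, make_brain_phantom, make_tensor_field, seed_tumor
from .solver import SimulationConfig, extract_mask, simulate
from .therapy import ChemotherapyPlan, RadiotherapyPlan
from .tissue import TissueParams, build_growth_tensor, scalar_diffusion_map


@dataclass
class OverlapReport:
    """Jaccard/Dice overlap with the raw voxel counts behind them."""

    jaccard: float
    dice: float
    n_pred: int
    n_truth: int
    n_intersection: int
    n_union: int


def _counts(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share a shape")
    inter = int(np.logical_and(pred, truth).sum())
    n_pred = int(pred.sum())
    n_truth = int(truth.sum())
    if n_pred == 0 and n_truth == 0:
        raise ValueError("both masks are empty; overlap is undefined")
    return n_pred, n_truth, inter, n_pred + n_truth - inter


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard score (intersection over union) of two binary masks."""
    _, _, inter, union = _counts(pred, truth)
    return inter / union


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient ``2 |S & GT| / (|S| + |GT|)`` of two binary masks."""
    n_pred, n_truth, inter, _ = _counts(pred, truth)
    return 2 * inter / (n_pred + n_truth)


def overlap_report(pred: np.ndarray, truth: np.ndarray) -> OverlapReport:
    n_pred, n_truth, inter, union = _counts(pred, truth)
    return OverlapReport(
        jaccard=inter / union,
        dice=2 * inter / (n_pred + n_truth),
        n_pred=n_pred,
        n_truth=n_truth,
        n_intersection=inter,
        n_union=union,
    )


@dataclass
class AblationScenario:
    """Everything needed to simulate one growth scenario reproducibly."""

    phantom_spec: PhantomSpec
    seed_center: tuple[float, float, float]
    seed_radius: float
    t_end: float
    rt_plan: RadiotherapyPlan | None = None
    chemo_plan: ChemotherapyPlan | None = None
    tissue_params: TissueParams | None = None
    config: SimulationConfig | None = None


STANDARD_VARIANTS = ("full", "no_chemo", "no_rt", "no_treatment", "no_dti", "no_viscoelastic")

_VARIANT_FLAGS = {
    "full": {},
    "no_chemo": {"use_chemo": False},
    "no_rt": {"use_rt": False},
    "no_treatment": {"use_rt": False, "use_chemo": False},
    "no_dti": {"use_dti": False},
    "no_viscoelastic": {"use_viscoelastic": False},
}


def run_ablation(
    scenario: AblationScenario, variants: tuple[str, ...] = STANDARD_VARIANTS
) -> pd.DataFrame:
    """Run the scenario under each variant and score against the full model.

    Returns a tidy table with columns ``variant, JS, DC, dJS_pct, dDC_pct``
    where the deltas are the percentage-point decrease from the full-model
    reference (which scores 1 by construction).
    """
    unknown = set(variants) - set(_VARIANT_FLAGS)
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")

    vol = make_brain_phantom(scenario.phantom_spec)
    dti = make_tensor_field(vol, scenario.phantom_spec)
    params = scenario.tissue_params or TissueParams()
    init = seed_tumor(vol, scenario.seed_center, scenario.seed_radius)
    base_config = scenario.config or SimulationConfig()
    base_config = replace(base_config, t_end=scenario.t_end)

    dbar_tensor = build_growth_tensor(dti, vol, params)
    dbar_scalar = scalar_diffusion_map(vol, params)

    def run(variant: str):
        cfg = replace(base_config, **_VARIANT_FLAGS[variant])
        dbar = dbar_scalar if not cfg.use_dti else dbar_tensor
        result = simulate(
            init, vol, dbar, params, cfg,
            rt_plan=scenario.rt_plan, chemo_plan=scenario.chemo_plan,
        )
        return extract_mask(result.final.u, cfg.u_detect)

    reference = run("full")
    rows = []
    for variant in variants:
        mask = reference if variant == "full" else run(variant)
        rep = overlap_report(mask, reference)
        rows.append(
            {
                "variant": variant,
                "JS": rep.jaccard,
                "DC": rep.dice,
                "dJS_pct": (1.0 - rep.jaccard) * 100.0,
                "dDC_pct": (1.0 - rep.dice) * 100.0,
            }
        )
    return pd.DataFrame(rows)
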