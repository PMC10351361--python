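"""Scenario orchestration and deformable dose accumulation.

Three treatment courses are simulated over a fraction series:

* **A** — the 3 mm setup-robust plan delivered unchanged every fraction;
* **B** — the non-robust plan delivered unchanged;
* **C** — the non-robust plan with daily online adaptation (partial
  spot-intensity re-optimization on each day's anatomy);

plus an **EXTENDED** course (1 mm-robust plan, no adaptation) used by the
setup-uncertainty linearity experiment.  Per-fraction dose is computed on
the daily (deformed, setup-shifted) anatomy, pulled back to the planning
grid through the ground-truth deformation, and summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .adaptation import AdaptationConfig, SpotSelection, reoptimize, select_spots
from .anatomy import FractionAnatomy, Phantom
from .dose import InfluenceMatrix, SpotSet, compute_dose, compute_influence
from .errors import ConfigurationError
from .planning import ObjectiveEvaluator, Plan, PlanObjectives

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the allowed (label, robustness, adapt) combinations."""

    label: str
    robust_mm: float
    adapt: bool

    _ALLOWED = {("A", 3.0, False), ("B", 0.0, False), ("C", 0.0, True),
                ("EXTENDED", 1.0, False)}

    def __post_init__(self):
        if (self.label, self.robust_mm, self.adapt) not in self._ALLOWED:
            raise ConfigurationError(
                "scenario must be A (3 mm robust, no adaptation), "
                "B (non-robust, no adaptation), C (non-robust, adapted) "
                "or EXTENDED (1 mm robust, no adaptation)"
            )


SCENARIO_A = ScenarioSpec("A", 3.0, False)
SCENARIO_B = ScenarioSpec("B", 0.0, False)
SCENARIO_C = ScenarioSpec("C", 0.0, True)
SCENARIO_EXTENDED = ScenarioSpec("EXTENDED", 1.0, False)


@dataclass
class AccumulatedDose:
    """Accumulated planning-grid dose with per-fraction provenance."""

    dose: np.ndarray
    provenance: list[dict]
    label: str


class DailyGeometryCache:
    """Caches daily influence matrices across scenarios sharing a series.

    Static fractions (zero shift, zero deformation) reuse the planning
    influence, which makes zero-motion courses reduce exactly to the static
    plan dose.
    """

    def __init__(self, phantom: Phantom, spots: SpotSet,
                 planning_influence: InfluenceMatrix):
        self.phantom = phantom
        self.spots = spots
        self.planning_influence = planning_influence
        self._store: dict[int, InfluenceMatrix] = {}

    def get(self, fraction: FractionAnatomy) -> InfluenceMatrix:
        if fraction.is_static:
            return self.planning_influence
        key = fraction.fraction_index
        if key not in self._store:
            daily = Phantom(
                self.phantom.grid_shape,
                self.phantom.spacing_mm,
                fraction.daily_density,
                self.phantom.origin_mm,
            )
            self._store[key] = compute_influence(
                daily, self.spots, fraction.setup_shift_mm
            )
        return self._store[key]


def fraction_dose(
    plan_weights: np.ndarray,
    fraction: FractionAnatomy,
    spots: SpotSet,
    n_fractions: int,
    phantom: Phantom,
    cache: DailyGeometryCache | None = None,
) -> np.ndarray:
    """Dose delivered at one fraction, on the daily grid.

    The full-course plan dose is divided uniformly over ``n_fractions``; the
    influence is computed on the daily density with the day's setup shift
    applied as an isocenter translation.
    """
    if n_fractions < 1:
        raise ConfigurationError("n_fractions must be >= 1")
    if cache is None:
        daily = Phantom(
            phantom.grid_shape, phantom.spacing_mm, fraction.daily_density,
            phantom.origin_mm,
        )
        influence = (
            compute_influence(daily, spots, fraction.setup_shift_mm)
            if not fraction.is_static
            else compute_influence(daily, spots)
        )
    else:
        influence = cache.get(fraction)
    return compute_dose(influence, plan_weights) / n_fractions


def map_to_planning(daily_dose: np.ndarray, fraction: FractionAnatomy) -> np.ndarray:
    """Pull a daily-grid dose back onto the planning grid.

    Planning voxel ``x`` receives the trilinear interpolation of the daily
    dose at ``x + u(x)`` (dose interpolation, not energy-mass transfer);
    positions mapped outside the daily grid contribute zero dose with a
    logged warning.
    """
    u = fraction.displacement_field_mm
    if daily_dose.shape != u.shape[1:]:
        raise ConfigurationError("daily dose shape does not match the fraction grid")
    if not np.any(u):
        return daily_dose.copy()
    spacing = np.asarray(fraction.spacing_mm, float).reshape(3, 1, 1, 1)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in daily_dose.shape], indexing="ij")
    ).astype(float)
    coords = idx + u / spacing
    upper = np.array(daily_dose.shape).reshape(3, 1, 1, 1) - 1
    if np.any(coords < 0) or np.any(coords > upper):
        log.warning(
            "fraction %d: deformation maps some voxels outside the daily grid; "
            "their dose contribution is zero",
            fraction.fraction_index,
        )
    return ndimage.map_coordinates(daily_dose, coords, order=1, mode="constant", cval=0.0)


def run_scenario(
    spec: ScenarioSpec,
    plans: dict[str, Plan],
    fractions: list[FractionAnatomy],
    phantom: Phantom,
    objectives: PlanObjectives | None = None,
    adaptation_config: AdaptationConfig | None = None,
    cache: DailyGeometryCache | None = None,
) -> AccumulatedDose:
    """Accumulate one scenario's course over a fraction series.

    ``plans`` maps ``"robust"``/``"nonrobust"`` (and optionally
    ``"robust_1mm"``) to optimized plans.  In scenario C the adapted subset is
    selected from the original planning weights and each day's re-optimization
    starts, per ``adaptation_config.start_from``, from the original plan
    (default) or from the previous day's adapted weights.
    """
    key = {"A": "robust", "B": "nonrobust", "C": "nonrobust",
           "EXTENDED": "robust_1mm"}[spec.label]
    if key not in plans:
        raise ConfigurationError(f"scenario {spec.label} requires a {key!r} plan")
    plan = plans[key]
    n = len(fractions)
    if n == 0:
        raise ConfigurationError("fraction series is empty")
    if cache is None:
        cache = DailyGeometryCache(
            phantom, plan.spots, compute_influence(phantom, plan.spots)
        )

    selection: SpotSelection | None = None
    acfg = adaptation_config or AdaptationConfig()
    if spec.adapt:
        objectives = objectives or PlanObjectives()
        selection = select_spots(plan.weights, acfg)

    total = np.zeros(phantom.grid_shape)
    provenance: list[dict] = []
    previous = plan.weights
    for fx in fractions:
        influence = cache.get(fx)
        weights = plan.weights
        record = {"fraction_index": fx.fraction_index}
        if spec.adapt:
            evaluator = ObjectiveEvaluator(fx.daily_structures, objectives)
            base = previous if acfg.start_from == "previous" else plan.weights
            adapted = reoptimize(
                influence, base, selection, fx.daily_structures, objectives, acfg
            )
            dose_flat = lambda w: np.asarray(influence.matrix @ w).ravel()
            record["objective_unadapted"] = float(evaluator(dose_flat(base)))
            record["objective_adapted"] = float(evaluator(dose_flat(adapted)))
            weights = adapted
            previous = adapted
        daily = compute_dose(influence, weights) / n
        total += map_to_planning(daily, fx)
        provenance.append(record)
    return AccumulatedDose(total, provenance, spec.label)
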