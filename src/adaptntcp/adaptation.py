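"""Online adaptation by partial spot-intensity re-optimization.

Each day the plan is adapted by re-optimizing only a subset of highly
weighted beamlets on that day's anatomy, keeping their positions and
energies fixed: the subset is the smallest set of spots carrying at least
33% of the total spot weight, padded so that it contains at least 10% of all
spots.  Re-optimization uses the original planning objectives; weights
outside the subset are left bit-exactly unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dose import InfluenceMatrix
from .errors import ConfigurationError, DomainError
from .planning import ObjectiveEvaluator, PlanObjectives
from .anatomy import StructureSet

log = logging.getLogger(__name__)


@dataclass
class AdaptationConfig:
    """Spot-selection fractions and re-optimization solver settings."""

    weight_fraction: float = 0.33
    count_fraction: float = 0.10
    max_iter: int = 200
    ftol: float = 1e-8
    start_from: str = "plan"  # or "previous": warm start of each day's solve

    def validate(self) -> None:
        for name in ("weight_fraction", "count_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        if self.start_from not in ("plan", "previous"):
            raise ConfigurationError("start_from must be 'plan' or 'previous'")


@dataclass
class SpotSelection:
    """The adapted spot subset (sorted indices) and the fractions it achieves."""

    indices: np.ndarray
    achieved_weight_fraction: float
    achieved_count_fraction: float


def select_spots(weights: np.ndarray, config: AdaptationConfig) -> SpotSelection:
    """Select the beamlet subset to re-optimize.

    Greedy scan in descending weight order (ties broken toward the lower spot
    index) until the cumulative weight reaches ``weight_fraction`` of the
    total — which provably yields the minimum-cardinality subset for a sum
    threshold — then padded with the next-heaviest spots until the subset
    holds at least ``ceil(count_fraction * n)`` spots.
    """
    config.validate()
    w = np.asarray(weights, float)
    if w.ndim != 1 or w.size == 0:
        raise ConfigurationError("weights must be a non-empty 1-D vector")
    if np.any(w < 0):
        raise DomainError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise DomainError("all spot weights are zero; nothing to adapt")

    order = np.argsort(-w, kind="stable")  # stable: lower index first on ties
    csum = np.cumsum(w[order])
    k_weight = int(np.searchsorted(csum, config.weight_fraction * total - 1e-12 * total)) + 1
    k_count = int(np.ceil(config.count_fraction * w.size - 1e-12))
    k = min(max(k_weight, k_count), w.size)
    chosen = np.sort(order[:k])
    return SpotSelection(
        indices=chosen,
        achieved_weight_fraction=float(w[chosen].sum() / total),
        achieved_count_fraction=float(k / w.size),
    )


def reoptimize(
    daily_influence: InfluenceMatrix,
    base_weights: np.ndarray,
    selection: SpotSelection,
    structures_daily: StructureSet,
    objectives: PlanObjectives,
    config: AdaptationConfig,
) -> np.ndarray:
    """Re-optimize the selected spot weights on the daily anatomy.

    Non-selected weights are returned bit-exactly equal to ``base_weights``.
    The base weights are a feasible start of the restricted problem, so the
    daily objective of the returned weights never exceeds that of the base
    (up to solver tolerance).
    """
    config.validate()
    base = np.asarray(base_weights, float)
    if base.size != daily_influence.n_spots:
        raise ConfigurationError("base_weights length must equal spot count")
    if np.any(base < 0):
        raise DomainError("base_weights must be >= 0")
    sel = np.asarray(selection.indices, int)
    if sel.size == 0 or sel.min() < 0 or sel.max() >= base.size:
        raise ConfigurationError("selection indices out of range")

    evaluator = ObjectiveEvaluator(structures_daily, objectives)
    mat = daily_influence.matrix
    mat_sel = mat[:, sel].tocsc()
    fixed_dose = np.asarray(mat @ base).ravel() - np.asarray(mat_sel @ base[sel]).ravel()

    def fg(ws: np.ndarray):
        dose = fixed_dose + np.asarray(mat_sel @ ws).ravel()
        f, gd = evaluator(dose, with_grad=True)
        return f, mat_sel.T @ gd

    res = optimize.minimize(
        fg,
        base[sel],
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * sel.size,
        options={"maxiter": config.max_iter, "ftol": config.ftol},
    )
    adapted = base.copy()
    adapted[sel] = np.maximum(res.x, 0.0)
    return adapted
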