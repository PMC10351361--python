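"""IMPT planning: spot placement and (robust) nonnegative weight optimization.

Two plans are built per patient: one robust to residual setup error via
discrete minimax over a scenario set of rigid isocenter shifts, and one with
no explicit setup robustness.  The optimization objective is a sum of
one-sided quadratic penalties encoding the clinical goals of a
simultaneously-integrated-boost head-and-neck protocol: per-voxel target
corridors at 95%-107% of the prescription (57 Gy low-risk / 70 Gy boost),
mean-dose limits for parotids (26 Gy), superior pharyngeal constrictor
(42 Gy) and larynx (40 Gy), per-voxel maximum-dose limits for spinal cord
(45 Gy) and brainstem (54 Gy), and small dose-minimization terms for the
oral cavity and esophagus.

The minimax problem ``min_w max_s f_s(w)`` over scenarios ``s`` is smoothed
with a temperature-scaled log-sum-exp (relative temperature 1e-3) and solved
with projected quasi-Newton iterations (L-BFGS-B with ``w >= 0`` bounds).
With a single (nominal) scenario the smoothed objective is identically the
plain objective, so single-scenario minimax reduces exactly to plain
optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .anatomy import Phantom, StructureSet
from .dose import InfluenceMatrix, SpotSet, Spot, beam_axes, _wed_map
from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class PlanObjectives:
    """Dose objectives and per-term penalty weights."""

    prescription_low: float = 57.0
    prescription_high: float = 70.0
    d98_pct: float = 95.0
    d2_pct: float = 107.0
    mean_limits: dict[str, float] = field(
        default_factory=lambda: {
            "PAROTID_CONTRA": 26.0,
            "PAROTID_IPSI": 26.0,
            "PCM_SUPERIOR": 42.0,
            "LARYNX": 40.0,
        }
    )
    max_limits: dict[str, float] = field(
        default_factory=lambda: {"SPINAL_CORD": 45.0, "BRAINSTEM": 54.0}
    )
    sparing_weights: dict[str, float] = field(
        default_factory=lambda: {"ORAL_MUCOSA": 0.02, "ESOPHAGUS": 0.02}
    )
    target_weight: float = 100.0
    mean_weight: float = 2.0
    max_weight: float = 5.0

    def validate(self) -> None:
        if self.prescription_low <= 0 or self.prescription_high <= 0:
            raise ConfigurationError("prescriptions must be > 0")
        for name in ("d98_pct", "d2_pct"):
            if not 0 < getattr(self, name) <= 200:
                raise ConfigurationError(f"{name} must lie in (0, 200]")


@dataclass
class RobustnessSetting:
    """Discrete setup-error scenario set for minimax optimization.

    ``scenario_shifts`` always contains the nominal (zero) scenario first;
    :meth:`isotropic` builds the standard 6 axis-aligned shifts plus nominal.
    """

    setup_uncertainty_mm: float
    scenario_shifts: list[np.ndarray]

    def __post_init__(self):
        if self.setup_uncertainty_mm < 0:
            raise ConfigurationError("setup_uncertainty_mm must be >= 0")
        shifts = [np.asarray(s, float) for s in self.scenario_shifts]
        if not shifts or np.any(shifts[0] != 0):
            shifts = [np.zeros(3)] + shifts
        for s in shifts:
            if np.linalg.norm(s) > self.setup_uncertainty_mm + 1e-9:
                raise ConfigurationError(
                    "scenario shift magnitude exceeds setup_uncertainty_mm"
                )
        self.scenario_shifts = shifts

    @classmethod
    def isotropic(cls, mm: float) -> "RobustnessSetting":
        if mm == 0:
            return cls(0.0, [])
        shifts = [sign * mm * np.eye(3)[ax] for ax in range(3) for sign in (+1, -1)]
        return cls(mm, shifts)


@dataclass
class Plan:
    """An optimized plan: spots + weights, robustness used, achieved objective."""

    spots: SpotSet
    robustness: RobustnessSetting
    objective_value: float
    objective_trace: list[float]
    converged: bool

    @property
    def weights(self) -> np.ndarray:
        return self.spots.weights


class ObjectiveEvaluator:
    """Binds structures + objectives to a grid for fast repeated evaluation."""

    def __init__(self, structures: StructureSet, objectives: PlanObjectives):
        objectives.validate()
        self.objectives = objectives
        self._terms: list[tuple[str, np.ndarray, float, float, str]] = []
        o = objectives

        def idx(role: str) -> np.ndarray:
            mask = structures.get(role)
            if mask is None:
                raise ConfigurationError(
                    f"objective references structure role {role!r} which is absent"
                )
            return np.flatnonzero(mask.ravel())

        for role, rx in (("CTV_LOW", o.prescription_low), ("CTV_HIGH", o.prescription_high)):
            i = idx(role)
            self._terms.append((role, i, o.d98_pct / 100.0 * rx, o.target_weight, "under"))
            self._terms.append((role, i, o.d2_pct / 100.0 * rx, o.target_weight, "overvox"))
        for role, lim in o.mean_limits.items():
            self._terms.append((role, idx(role), lim, o.mean_weight, "mean"))
        for role, lim in o.max_limits.items():
            self._terms.append((role, idx(role), lim, o.max_weight, "overvox"))
        for role, w in o.sparing_weights.items():
            self._terms.append((role, idx(role), 0.0, w, "sparing"))

    def __call__(self, dose_flat: np.ndarray, with_grad: bool = False):
        """Penalty value (and optionally its gradient w.r.t. voxel dose)."""
        value = 0.0
        grad = np.zeros_like(dose_flat) if with_grad else None
        for _, i, threshold, weight, kind in self._terms:
            d = dose_flat[i]
            n = d.size
            if kind == "under":
                r = np.maximum(threshold - d, 0.0)
                value += weight * np.dot(r, r) / n
                if with_grad:
                    np.add.at(grad, i, -2.0 * weight / n * r)
            elif kind == "overvox":
                r = np.maximum(d - threshold, 0.0)
                value += weight * np.dot(r, r) / n
                if with_grad:
                    np.add.at(grad, i, 2.0 * weight / n * r)
            elif kind == "mean":
                excess = max(d.mean() - threshold, 0.0)
                value += weight * excess**2
                if with_grad and excess > 0:
                    np.add.at(grad, i, np.full(n, 2.0 * weight * excess / n))
            else:  # sparing: plain quadratic pull toward zero dose
                value += weight * np.dot(d, d) / n
                if with_grad:
                    np.add.at(grad, i, 2.0 * weight / n * d)
        return (value, grad) if with_grad else value


def evaluate_objective(
    dose: np.ndarray, structures: StructureSet, objectives: PlanObjectives
) -> float:
    """Scalar planning penalty of a dose grid (zero when every constraint is
    met and the sparing organs receive no dose)."""
    return float(ObjectiveEvaluator(structures, objectives)(np.ravel(dose)))


def place_spots(
    phantom: Phantom,
    structures: StructureSet,
    angles: tuple[float, ...] = (60.0, 180.0, 300.0),
    lateral_spacing_mm: float = 7.0,
    energy_layer_spacing_mm: float = 7.0,
) -> SpotSet:
    """Place spots covering both CTVs from each beam angle.

    A BEV lateral grid at ``lateral_spacing_mm`` covers the target extent and
    energy layers at ``energy_layer_spacing_mm`` cover its water-equivalent
    depth extent; a spot is kept when some target voxel lies within one
    lateral spacing of its axis and one layer spacing of its range.
    Deterministic; initial weights are 1.
    """
    if lateral_spacing_mm <= 0 or energy_layer_spacing_mm <= 0:
        raise ConfigurationError("spot spacings must be > 0")
    target = structures["CTV_LOW"] | structures["CTV_HIGH"]
    if not target.any():
        raise ConfigurationError("CTV_LOW is empty; nothing to cover")

    X, Y, Z = phantom.voxel_centers()
    iso = phantom.center_mm
    pts = np.stack([X[target], Y[target], Z[target]], axis=1)

    spots: list[Spot] = []
    sid = 0
    for angle in angles:
        _, e_u = beam_axes(angle)
        u = (pts[:, 0] - iso[0]) * e_u[0] + (pts[:, 1] - iso[1]) * e_u[1]
        zc = pts[:, 2] - iso[2]
        wed = _wed_map(phantom, angle)[target]

        def _axis(vals, step):
            lo, hi = vals.min(), vals.max()
            n = max(int(np.ceil((hi - lo) / step)) + 1, 1)
            return (lo + hi) / 2.0 + step * (np.arange(n) - (n - 1) / 2.0)

        for us in _axis(u, lateral_spacing_mm):
            for zs in _axis(zc, lateral_spacing_mm):
                lat2 = (u - us) ** 2 + (zc - zs) ** 2
                near = lat2 <= lateral_spacing_mm**2
                if not near.any():
                    continue
                for r in _axis(wed[near], energy_layer_spacing_mm):
                    if np.any(np.abs(wed[near] - r) <= energy_layer_spacing_mm) and r > 0:
                        spots.append(Spot(angle, (float(us), float(zs)), float(r), sid))
                        sid += 1
    return SpotSet(spots, np.ones(len(spots)))


def optimize_weights(
    influences: list[InfluenceMatrix],
    structures: StructureSet,
    objectives: PlanObjectives,
    robustness: RobustnessSetting,
    *,
    x0: np.ndarray | None = None,
    max_iter: int = 500,
    ftol: float = 1e-6,
    temperature_rel: float = 1e-3,
    spots: SpotSet | None = None,
) -> Plan:
    """Minimax-optimal nonnegative spot weights over the scenario influences.

    ``influences[k]`` must be the dose operator under ``robustness.
    scenario_shifts[k]`` (nominal first), all sharing one spot ordering.
    Minimizes a log-sum-exp smoothed worst-case objective with projected
    quasi-Newton steps; with a single scenario this is exactly plain
    optimization.  Starting from a caller-supplied ``x0``, the returned
    objective never exceeds the objective of that warm start (monotone
    line-search descent).  On hitting the iteration cap the best iterate is
    returned with ``converged=False`` and a logged warning.
    """
    if len(influences) < 1:
        raise ConfigurationError("at least one scenario influence is required")
    if len(influences) != len(robustness.scenario_shifts):
        raise ConfigurationError(
            "one influence matrix per scenario shift is required "
            f"({len(influences)} vs {len(robustness.scenario_shifts)})"
        )
    n_spots = influences[0].n_spots
    if any(m.n_spots != n_spots for m in influences):
        raise ConfigurationError("scenario influences must share the spot ordering")

    evaluator = ObjectiveEvaluator(structures, objectives)
    mats = [m.matrix for m in influences]

    if x0 is None:
        # scale a uniform start so the nominal boost-CTV mean hits prescription
        d1 = np.asarray(mats[0] @ np.ones(n_spots)).ravel()
        ref = d1[structures["CTV_HIGH"].ravel()].mean()
        x0 = np.full(n_spots, objectives.prescription_high / max(ref, 1e-12))
    x0 = np.maximum(np.asarray(x0, float), 0.0)

    def fg(w: np.ndarray):
        fs, gs = [], []
        for mat in mats:
            f, gd = evaluator(np.asarray(mat @ w).ravel(), with_grad=True)
            fs.append(f)
            gs.append(mat.T @ gd)
        fs = np.array(fs)
        if len(fs) == 1:
            return fs[0], gs[0]
        m = fs.max()
        tau = temperature_rel * max(abs(m), 1e-12)
        e = np.exp((fs - m) / tau)
        coef = e / e.sum()
        value = m + tau * np.log(e.sum())
        return value, sum(c * g for c, g in zip(coef, gs))

    trace: list[float] = []
    res = optimize.minimize(
        fg,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * n_spots,
        callback=lambda w: trace.append(fg(w)[0]),
        options={"maxiter": max_iter, "ftol": ftol, "maxcor": 20},
    )
    converged = bool(res.success) or res.status == 0
    if not converged:
        log.warning("weight optimization hit the iteration cap: %s", res.message)
    weights = np.maximum(res.x, 0.0)
    worst = max(
        evaluator(np.asarray(mat @ weights).ravel()) for mat in mats
    )
    if spots is not None:
        spot_set = spots.with_weights(weights)
    else:  # placeholder geometry for weight-space-only use
        spot_set = SpotSet(
            [Spot(0.0, (0.0, 0.0), 1.0, j) for j in range(n_spots)], weights
        )
    return Plan(spot_set, robustness, float(worst), trace, converged)


def worst_case_objective(
    plan_weights: np.ndarray,
    influences: list[InfluenceMatrix],
    structures: StructureSet,
    objectives: PlanObjectives,
) -> float:
    """Max of the planning objective over a list of scenario influences."""
    evaluator = ObjectiveEvaluator(structures, objectives)
    return max(
        float(evaluator(np.asarray(m.matrix @ plan_weights).ravel()))
        for m in influences
    )
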