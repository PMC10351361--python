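"""End-to-end orchestration: simulate -> plan -> scenarios -> NTCP -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accumulation import (
    SCENARIO_A,
    SCENARIO_B,
    SCENARIO_C,
    AccumulatedDose,
    DailyGeometryCache,
    run_scenario,
)
from .adaptation import AdaptationConfig
from .anatomy import CohortConfig, generate_fraction_series, generate_phantom
from .dose import compute_influence
from .ntcp import ScenarioNTCP, default_registry, evaluate_all
from .planning import (
    Plan,
    PlanObjectives,
    RobustnessSetting,
    optimize_weights,
    place_spots,
)
from .report import (
    DeltaNTCPReport,
    SignificanceRule,
    cohort_report,
    delta_ntcp,
)

log = logging.getLogger(__name__)


@dataclass
class PatientResult:
    patient_id: int
    plans: dict[str, Plan]
    accumulated: dict[str, AccumulatedDose]
    ntcp: dict[str, ScenarioNTCP]
    report: DeltaNTCPReport
    n_fractions: int


def build_plans(
    phantom,
    structures,
    spots=None,
    objectives: PlanObjectives | None = None,
    robust_mm: float = 3.0,
):
    """Optimize the robust and non-robust plan pair on one phantom."""
    objectives = objectives or PlanObjectives()
    if spots is None:
        spots = place_spots(phantom, structures)
    nominal = compute_influence(phantom, spots)

    robustness = RobustnessSetting.isotropic(robust_mm)
    influences = [nominal] + [
        compute_influence(phantom, spots, s) for s in robustness.scenario_shifts[1:]
    ]
    plan_robust = optimize_weights(
        influences, structures, objectives, robustness, spots=spots
    )
    plan_nonrobust = optimize_weights(
        [nominal], structures, objectives, RobustnessSetting.isotropic(0.0),
        spots=spots,
    )
    return {"robust": plan_robust, "nonrobust": plan_nonrobust}, nominal, spots


def run_patient(
    config: CohortConfig,
    patient_index: int,
    objectives: PlanObjectives | None = None,
    adaptation: AdaptationConfig | None = None,
    registry=None,
) -> PatientResult:
    """Simulate one patient end to end and compute the ΔNTCP report."""
    objectives = objectives or PlanObjectives()
    phantom, structures = generate_phantom(config, patient_index)
    plans, nominal, spots = build_plans(phantom, structures, objectives=objectives)
    fractions = generate_fraction_series(phantom, structures, config, patient_index)
    cache = DailyGeometryCache(phantom, spots, nominal)

    accumulated: dict[str, AccumulatedDose] = {}
    ntcp: dict[str, ScenarioNTCP] = {}
    for spec in (SCENARIO_A, SCENARIO_B, SCENARIO_C):
        acc = run_scenario(
            spec, plans, fractions, phantom,
            objectives=objectives, adaptation_config=adaptation, cache=cache,
        )
        accumulated[spec.label] = acc
        ntcp[spec.label] = evaluate_all(
            acc.dose, structures, registry, label=spec.label
        )
    report = delta_ntcp(ntcp["A"], ntcp["B"], ntcp["C"], patient_id=patient_index)
    return PatientResult(
        patient_index, plans, accumulated, ntcp, report, len(fractions)
    )


def run_cohort(
    config: CohortConfig,
    objectives: PlanObjectives | None = None,
    adaptation: AdaptationConfig | None = None,
    registry=None,
    rule: SignificanceRule | None = None,
    keep_doses: bool = False,
) -> dict:
    """Simulate the whole cohort and aggregate the ΔNTCP analysis.

    Returns the :func:`adaptntcp.report.cohort_report` dict augmented with
    the per-patient reports, the per-scenario NTCP table and (optionally)
    the per-patient results with accumulated dose grids.
    """
    registry = registry if registry is not None else default_registry()
    reports = []
    ntcp_rows = []
    results = []
    for i in range(config.n_patients):
        log.info("patient %d/%d", i + 1, config.n_patients)
        res = run_patient(config, i, objectives, adaptation, registry)
        reports.append(res.report)
        for label, sn in res.ntcp.items():
            for endpoint, value in sn.values.items():
                ntcp_rows.append({
                    "patient": i,
                    "scenario": label,
                    "endpoint": endpoint,
                    "ntcp_pct": None if value is None else 100.0 * value,
                })
        if not keep_doses:
            for acc in res.accumulated.values():
                acc.dose = np.empty(0)  # keep provenance, drop the grids
        results.append(res)
    out = cohort_report(reports, rule)
    out["reports"] = reports
    out["ntcp_by_scenario"] = pd.DataFrame(ntcp_rows)
    out["patients"] = results
    return out
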