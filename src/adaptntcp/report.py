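"""Headline analysis quantities: per-mechanism NTCP reductions and verdicts.

For each patient the three accumulated courses A (robust, unadapted),
B (non-robust, unadapted) and C (non-robust, adapted) yield per-endpoint
NTCP values, from which the toxicity reduction attributable to each
mechanism follows:

    dNTCP_SUR      = NTCP_B - NTCP_A      (setup-uncertainty reduction)
    dNTCP_AGC      = NTCP_C - NTCP_B      (adaptation to geometric changes)
    dNTCP_SUR&AGC  = NTCP_C - NTCP_A      (both combined)

expressed in percentage points (pp = 100 x probability difference); the
additivity identity dSUR + dAGC = dSUR&AGC holds algebraically and is
asserted on every report.  The "any-of-four" total combines xerostomia,
dysphagia, aspiration and oral mucositis under an independence assumption,
P(any) = 1 - prod(1 - p_i); the plain sum of per-endpoint reductions is
exported alongside, and every export header records which combination rule
was used.  Clinical significance per mechanism follows a configurable
two-branch rule modeled on model-based patient-selection criteria: a single
endpoint reduced by >= 10 pp, or summed reductions >= 15 pp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ntcp import MAIN_ENDPOINTS, ScenarioNTCP

MECHANISMS = ("sur", "agc", "sur_agc")
COMBINATION_RULE = "any-of-four: 1 - prod(1 - p_i), independence assumed"


@dataclass
class SignificanceRule:
    """Thresholds (pp) for a clinically meaningful NTCP reduction."""

    single_threshold_pp: float = 10.0
    summed_threshold_pp: float = 15.0
    endpoints: tuple[str, ...] = MAIN_ENDPOINTS

    def __post_init__(self):
        if self.single_threshold_pp <= 0 or self.summed_threshold_pp <= 0:
            raise ConfigurationError("significance thresholds must be > 0")


@dataclass
class DeltaNTCPReport:
    """Per-patient NTCP reductions (pp) per endpoint and mechanism."""

    patient_id: int
    deltas_pp: dict[str, dict[str, float]]      # endpoint -> mechanism -> pp
    excluded: dict[str, str]                    # endpoint -> reason
    scenario_ntcp: dict[str, dict[str, float | None]]  # label -> endpoint -> prob
    total_any_pp: dict[str, float | None]       # mechanism -> pp (any-of-four)
    total_sum_pp: dict[str, float | None]       # mechanism -> pp (plain sum)
    combination_rule: str = COMBINATION_RULE


def total_any_toxicity(probabilities) -> float:
    """P(any of the endpoints occurs) under independence:
    ``1 - prod(1 - p_i)``."""
    p = np.asarray(list(probabilities), float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def delta_ntcp(
    ntcp_a: ScenarioNTCP,
    ntcp_b: ScenarioNTCP,
    ntcp_c: ScenarioNTCP,
    patient_id: int = 0,
) -> DeltaNTCPReport:
    """Per-endpoint NTCP reductions between the three scenario courses.

    Endpoints evaluable in some scenarios but not others are flagged
    inconsistent and excluded.  The additivity identity of the three
    differences is asserted to machine precision.
    """
    by_label = {"A": ntcp_a, "B": ntcp_b, "C": ntcp_c}
    endpoints = list(ntcp_a.values)
    deltas: dict[str, dict[str, float]] = {}
    excluded: dict[str, str] = {}
    for e in endpoints:
        vals = [by_label[s].values.get(e) for s in "ABC"]
        if all(v is None for v in vals):
            excluded[e] = next(
                (s.not_evaluable.get(e) for s in by_label.values()
                 if s.not_evaluable.get(e)), "not evaluable",
            )
            continue
        if any(v is None for v in vals):
            excluded[e] = "inconsistent: evaluable in some scenarios only"
            continue
        a, b, c = vals
        d = {"sur": 100.0 * (b - a), "agc": 100.0 * (c - b),
             "sur_agc": 100.0 * (c - a)}
        assert abs(d["sur"] + d["agc"] - d["sur_agc"]) <= 1e-9 * max(
            1.0, abs(d["sur_agc"])
        ), "additivity identity violated"
        deltas[e] = d

    total_any: dict[str, float | None] = {}
    total_sum: dict[str, float | None] = {}
    main_ok = all(
        by_label[s].values.get(e) is not None
        for e in MAIN_ENDPOINTS for s in "ABC"
    )
    if main_ok:
        p_any = {
            s: total_any_toxicity(
                [by_label[s].values[e] for e in MAIN_ENDPOINTS]
            )
            for s in "ABC"
        }
        total_any = {
            "sur": 100.0 * (p_any["B"] - p_any["A"]),
            "agc": 100.0 * (p_any["C"] - p_any["B"]),
            "sur_agc": 100.0 * (p_any["C"] - p_any["A"]),
        }
        total_sum = {
            mech: sum(deltas[e][mech] for e in MAIN_ENDPOINTS)
            for mech in MECHANISMS
        }
    else:
        total_any = dict.fromkeys(MECHANISMS)
        total_sum = dict.fromkeys(MECHANISMS)

    return DeltaNTCPReport(
        patient_id=patient_id,
        deltas_pp=deltas,
        excluded=excluded,
        scenario_ntcp={s: dict(by_label[s].values) for s in "ABC"},
        total_any_pp=total_any,
        total_sum_pp=total_sum,
    )


def classify_significance(
    report: DeltaNTCPReport, rule: SignificanceRule | None = None
) -> dict[str, dict]:
    """Clinical-significance verdict per mechanism.

    A mechanism qualifies when any single participating endpoint is reduced
    by at least the single-endpoint threshold, or the summed reductions over
    participating endpoints reach the summed threshold.  The verdict records
    which branch fired.
    """
    rule = rule or SignificanceRule()
    verdicts: dict[str, dict] = {}
    for mech in MECHANISMS:
        reductions = {
            e: -report.deltas_pp[e][mech]
            for e in rule.endpoints
            if e in report.deltas_pp
        }
        max_single = max(reductions.values(), default=0.0)
        summed = sum(reductions.values())
        if max_single >= rule.single_threshold_pp:
            verdict, branch = True, "single-endpoint"
        elif summed >= rule.summed_threshold_pp:
            verdict, branch = True, "summed"
        else:
            verdict, branch = False, "none"
        verdicts[mech] = {
            "significant": verdict,
            "branch": branch,
            "max_single_reduction_pp": max_single,
            "summed_reduction_pp": summed,
            "n_endpoints": len(reductions),
        }
    return verdicts


def linearity_experiment(
    phantom,
    structures,
    fractions,
    settings_mm=(0.0, 1.0, 3.0),
    objectives=None,
    registry=None,
    cache=None,
    spots=None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """NTCP of the unadapted accumulated course versus setup-robustness
    setting.

    For each setting a plan is optimized (minimax over the corresponding
    isotropic scenario set; plain optimization at 0 mm) and delivered without
    adaptation over the fraction series.  Returns a table of per-endpoint
    NTCP (percent) per setting and, for three or more settings, each
    endpoint's interpolation residual of the middle setting against the line
    through the first and last — small residuals support a locally linear
    NTCP-versus-setting relationship.
    """
    from .accumulation import DailyGeometryCache, SCENARIO_B, run_scenario
    from .dose import compute_influence
    from .ntcp import evaluate_all
    from .planning import PlanObjectives, RobustnessSetting, optimize_weights, place_spots

    objectives = objectives or PlanObjectives()
    if spots is None:
        spots = place_spots(phantom, structures)
    nominal = compute_influence(phantom, spots)
    if cache is None:
        cache = DailyGeometryCache(phantom, spots, nominal)

    settings = list(settings_mm)
    rows = []
    per_setting: dict[float, ScenarioNTCP] = {}
    for mm in settings:
        if mm in per_setting:
            continue
        robustness = RobustnessSetting.isotropic(mm)
        influences = [nominal] + [
            compute_influence(phantom, spots, s)
            for s in robustness.scenario_shifts[1:]
        ]
        plan = optimize_weights(
            influences, structures, objectives, robustness, spots=spots
        )
        acc = run_scenario(
            SCENARIO_B, {"nonrobust": plan}, fractions, phantom,
            objectives=objectives, cache=cache,
        )
        per_setting[mm] = evaluate_all(acc.dose, structures, registry, label=f"{mm}mm")
    for mm in settings:
        for e, v in per_setting[mm].values.items():
            rows.append({
                "setting_mm": mm,
                "endpoint": e,
                "ntcp_pct": None if v is None else 100.0 * v,
            })
    table = pd.DataFrame(rows)

    residuals: dict[str, float] = {}
    if len(settings) >= 3 and settings[0] != settings[-1]:
        lo, mid, hi = settings[0], settings[len(settings) // 2], settings[-1]
        for e in per_setting[lo].values:
            v0, vm, v1 = (per_setting[s].values[e] for s in (lo, mid, hi))
            if None in (v0, vm, v1):
                continue
            t = (mid - lo) / (hi - lo)
            residuals[e] = 100.0 * (vm - ((1 - t) * v0 + t * v1))
    return table, residuals


def cohort_report(
    reports: list[DeltaNTCPReport], rule: SignificanceRule | None = None
):
    """Cohort summary: per-endpoint mean reductions over evaluable patients,
    per-patient totals, and significance counts per mechanism."""
    if not reports:
        raise ConfigurationError("cohort is empty")
    rule = rule or SignificanceRule()

    rows = []
    for r in reports:
        for e, d in r.deltas_pp.items():
            for mech in MECHANISMS:
                rows.append({
                    "patient": r.patient_id, "endpoint": e,
                    "mechanism": mech, "delta_ntcp_pp": d[mech],
                })
    per_patient = pd.DataFrame(rows)
    summary = (
        per_patient.groupby(["endpoint", "mechanism"])["delta_ntcp_pp"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_delta_ntcp_pp", "count": "n_evaluable"})
    )

    totals = pd.DataFrame([
        {"patient": r.patient_id, "mechanism": mech,
         "total_any_pp": r.total_any_pp[mech], "total_sum_pp": r.total_sum_pp[mech]}
        for r in reports for mech in MECHANISMS
    ])

    counts = dict.fromkeys(MECHANISMS, 0)
    verdict_rows = []
    for r in reports:
        v = classify_significance(r, rule)
        for mech in MECHANISMS:
            counts[mech] += int(v[mech]["significant"])
            verdict_rows.append({
                "patient": r.patient_id, "mechanism": mech, **v[mech],
            })
    verdicts = pd.DataFrame(verdict_rows)
    return {
        "per_patient": per_patient,
        "summary": summary,
        "totals": totals,
        "verdicts": verdicts,
        "significance_counts": counts,
        "combination_rule": COMBINATION_RULE,
    }
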