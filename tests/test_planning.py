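"""Planning contracts: objective arithmetic, spot coverage, minimax optimality."""

import numpy as np
import pytest
from scipy import optimize, sparse

from adaptntcp import (
    PlanObjectives,
    RobustnessSetting,
    compute_influence,
    evaluate_objective,
    optimize_weights,
    place_spots,
    worst_case_objective,
)
from adaptntcp.anatomy import Phantom, StructureSet
from adaptntcp.dose import InfluenceMatrix
from adaptntcp.errors import ConfigurationError
from adaptntcp.planning import ObjectiveEvaluator


def prescription_dose(phantom, structures, objectives):
    dose = np.zeros(phantom.grid_shape)
    dose[structures["CTV_LOW"]] = objectives.prescription_low
    dose[structures["CTV_HIGH"]] = objectives.prescription_high
    return dose


class TestObjective:
    def test_exact_prescription_scores_zero(self, tiny_patient):
        phantom, structures = tiny_patient
        obj = PlanObjectives()
        dose = prescription_dose(phantom, structures, obj)
        # targets exactly at prescription, OARs unirradiated (targets are
        # disjoint from every constrained or sparing organ in this phantom
        # except possibly partial overlaps; zero them to be exact)
        for role in list(obj.mean_limits) + list(obj.max_limits) + list(obj.sparing_weights):
            dose[structures[role]] = 0.0
        dose[structures["CTV_LOW"]] = obj.prescription_low
        dose[structures["CTV_HIGH"]] = obj.prescription_high
        assert evaluate_objective(dose, structures, obj) == 0.0

    def test_parotid_mean_excess_hand_value(self, tiny_patient):
        """Uniform 30 Gy on a 26 Gy mean-limit organ adds weight*(30-26)^2."""
        phantom, structures = tiny_patient
        obj = PlanObjectives()
        dose = prescription_dose(phantom, structures, obj)
        base = evaluate_objective(dose, structures, obj)
        with_parotid = dose.copy()
        with_parotid[structures["PAROTID_CONTRA"] & ~structures["CTV_HIGH"]
                     & ~structures["CTV_LOW"]] = 30.0
        got = evaluate_objective(with_parotid, structures, obj)
        assert got - base == pytest.approx(obj.mean_weight * (30.0 - 26.0) ** 2, rel=1e-12)

    def test_dose_outside_structures_is_free(self, tiny_patient):
        phantom, structures = tiny_patient
        obj = PlanObjectives()
        dose = prescription_dose(phantom, structures, obj)
        outside = np.ones(phantom.grid_shape, bool)
        for role in structures.roles:
            outside &= ~structures[role]
        bumped = dose.copy()
        bumped[outside] += 25.0
        assert evaluate_objective(bumped, structures, obj) == evaluate_objective(
            dose, structures, obj
        )

    def test_missing_structure_named_in_error(self, tiny_patient):
        phantom, structures = tiny_patient
        masks = {r: structures[r] for r in structures.roles if r != "BRAINSTEM"}
        with pytest.raises(ConfigurationError, match="BRAINSTEM"):
            evaluate_objective(
                np.zeros(phantom.grid_shape), StructureSet(masks), PlanObjectives()
            )

    def test_gradient_matches_finite_differences(self, tiny_patient, rng):
        phantom, structures = tiny_patient
        ev = ObjectiveEvaluator(structures, PlanObjectives())
        d = 70.0 * rng.random(phantom.n_voxels)
        f0, g = ev(d, with_grad=True)
        for i in rng.integers(0, d.size, 5):
            eps = 1e-4
            dp = d.copy(); dp[i] += eps
            dm = d.copy(); dm[i] -= eps
            fd = (ev(dp) - ev(dm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestPlaceSpots:
    def test_deterministic(self, tiny_patient):
        phantom, structures = tiny_patient
        a = place_spots(phantom, structures)
        b = place_spots(phantom, structures)
        assert len(a) == len(b)
        assert all(x == y for x, y in zip(a.spots, b.spots))

    def test_single_voxel_target_gets_a_peaked_spot(self):
        shape = (24, 24, 8)
        spacing = np.full(3, 2.0)
        origin = -spacing * (np.array(shape) - 1) / 2
        phantom = Phantom(shape, spacing, np.ones(shape), origin)
        mask = np.zeros(shape, bool)
        mask[12, 12, 4] = True
        structures = StructureSet({"CTV_HIGH": mask, "CTV_LOW": mask})
        spots = place_spots(phantom, structures, angles=(180.0,))
        assert len(spots) >= 1
        infl = compute_influence(phantom, spots)
        peaked = [
            np.unravel_index(int(np.argmax(infl.matrix[:, j].toarray())), shape)
            for j in range(len(spots))
        ]
        assert (12, 12, 4) in peaked

    def test_every_target_voxel_within_one_spacing_of_a_spot_axis(self, tiny_patient):
        phantom, structures = tiny_patient
        spacing = 7.0
        spots = place_spots(phantom, structures, lateral_spacing_mm=spacing)
        from adaptntcp.dose import beam_axes

        X, Y, Z = phantom.voxel_centers()
        target = structures["CTV_LOW"] | structures["CTV_HIGH"]
        iso = phantom.center_mm
        for angle in (60.0, 180.0, 300.0):
            _, e_u = beam_axes(angle)
            u = (X[target] - iso[0]) * e_u[0] + (Y[target] - iso[1]) * e_u[1]
            zc = Z[target] - iso[2]
            axes = np.array(
                [s.lateral_position_mm for s in spots.spots if s.beam_angle_deg == angle]
            )
            d2 = (u[:, None] - axes[None, :, 0]) ** 2 + (
                zc[:, None] - axes[None, :, 1]
            ) ** 2
            assert np.all(d2.min(axis=1) <= spacing**2 + 1e-9)

    def test_halving_lateral_spacing_at_least_doubles_slab_spot_count(self):
        shape = (32, 32, 8)
        spacing = np.full(3, 2.0)
        origin = -spacing * (np.array(shape) - 1) / 2
        phantom = Phantom(shape, spacing, np.ones(shape), origin)
        slab = np.zeros(shape, bool)
        slab[8:24, 14:18, 2:6] = True
        structures = StructureSet({"CTV_HIGH": slab, "CTV_LOW": slab})
        n_coarse = len(place_spots(phantom, structures, angles=(180.0,),
                                   lateral_spacing_mm=8.0))
        n_fine = len(place_spots(phantom, structures, angles=(180.0,),
                                 lateral_spacing_mm=4.0))
        assert n_fine >= 2 * n_coarse

    def test_invalid_spacing_rejected(self, tiny_patient):
        phantom, structures = tiny_patient
        with pytest.raises(ConfigurationError):
            place_spots(phantom, structures, lateral_spacing_mm=0.0)


def toy_target_problem(d=0.5, prescription=70.0):
    """One voxel, one spot with influence d; target-only objectives."""
    grid = (1, 1, 1)
    mask = np.ones(grid, bool)
    structures = StructureSet({"CTV_HIGH": mask, "CTV_LOW": mask})
    obj = PlanObjectives(mean_limits={}, max_limits={}, sparing_weights={},
                         prescription_low=prescription, prescription_high=prescription)
    mat = sparse.csc_matrix(np.array([[d]]))
    infl = InfluenceMatrix(mat, grid, np.full(3, 2.0))
    return infl, structures, obj


class TestOptimizeWeights:
    def test_single_voxel_closed_form(self):
        """Optimal weight drives the voxel into the 95%-107% prescription
        corridor around p/d (the corridor objective's analytic minimizer)."""
        d, p = 0.5, 70.0
        infl, structures, obj = toy_target_problem(d, p)
        plan = optimize_weights(
            [infl], structures, obj, RobustnessSetting.isotropic(0.0)
        )
        assert plan.objective_value == pytest.approx(0.0, abs=1e-10)
        assert 0.95 * p / d <= plan.weights[0] <= 1.07 * p / d
        assert plan.weights[0] == pytest.approx(p / d, rel=0.07)

    def test_single_scenario_minimax_equals_plain_optimization(self, tiny_patient,
                                                               tiny_plans):
        """Minimax over {nominal} must coincide with an independently coded
        plain solve of the same bound-constrained problem."""
        phantom, structures = tiny_patient
        _, nominal, spots = tiny_plans
        obj = PlanObjectives()
        x0 = np.full(len(spots), 0.5)
        plan = optimize_weights(
            [nominal], structures, obj, RobustnessSetting.isotropic(0.0),
            x0=x0, spots=spots,
        )
        ev = ObjectiveEvaluator(structures, obj)
        mat = nominal.matrix

        def fg(w):
            f, gd = ev(np.asarray(mat @ w).ravel(), with_grad=True)
            return f, mat.T @ gd

        res = optimize.minimize(
            fg, x0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * len(spots),
            options={"maxiter": 500, "ftol": 1e-6, "maxcor": 20},
        )
        np.testing.assert_array_equal(plan.weights, np.maximum(res.x, 0.0))

    def test_weights_nonnegative_and_trace_monotone(self, tiny_plans):
        plans, _, _ = tiny_plans
        for plan in plans.values():
            assert np.all(plan.weights >= 0)
            trace = np.array(plan.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_robust_plan_wins_worst_case(self, tiny_patient, tiny_plans):
        """Minimax optimality: over the +-3 mm scenario set the robust plan's
        worst case cannot exceed the non-robust plan's worst case."""
        phantom, structures = tiny_patient
        plans, nominal, spots = tiny_plans
        obj = PlanObjectives()
        shifts = RobustnessSetting.isotropic(3.0).scenario_shifts
        influences = [nominal] + [
            compute_influence(phantom, spots, s) for s in shifts[1:]
        ]
        worst_robust = worst_case_objective(
            plans["robust"].weights, influences, structures, obj
        )
        worst_nonrobust = worst_case_objective(
            plans["nonrobust"].weights, influences, structures, obj
        )
        assert worst_robust <= worst_nonrobust

    def test_warm_start_never_worsened(self, tiny_patient, tiny_plans, rng):
        phantom, structures = tiny_patient
        _, nominal, spots = tiny_plans
        obj = PlanObjectives()
        setting = RobustnessSetting.isotropic(0.0)
        x0 = rng.random(len(spots))
        start = evaluate_objective(
            (nominal.matrix @ x0).reshape(phantom.grid_shape), structures, obj
        )
        plan = optimize_weights([nominal], structures, obj, setting, x0=x0)
        assert plan.objective_value <= start + 1e-9 * max(1.0, start)

    def test_scenario_count_mismatch_rejected(self, tiny_patient, tiny_plans):
        _, structures = tiny_patient
        _, nominal, _ = tiny_plans
        with pytest.raises(ConfigurationError):
            optimize_weights(
                [nominal], structures, PlanObjectives(),
                RobustnessSetting.isotropic(3.0),
            )


def test_robustness_setting_invariants():
    setting = RobustnessSetting.isotropic(3.0)
    assert len(setting.scenario_shifts) == 7
    assert not setting.scenario_shifts[0].any()  # nominal always included
    with pytest.raises(ConfigurationError):
        RobustnessSetting(1.0, [np.array([3.0, 0.0, 0.0])])
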