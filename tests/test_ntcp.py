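"""DVH/gEUD metrics and the six toxicity models against closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from adaptntcp import (
    default_registry,
    dvh_metrics,
    evaluate_all,
    geud,
    ntcp_logistic_d50k,
    ntcp_multivar_logistic,
    ntcp_probit_geud,
)
from adaptntcp.errors import ConfigurationError, DomainError
from adaptntcp.ntcp import (
    NTCPModelSpec,
    d_percent,
    registry_from_yaml,
    registry_to_yaml,
)


def brute_force_d_percent(doses, p):
    """Oracle: scan the attained doses for the smallest d with
    frac(volume >= d) <= p/100."""
    doses = np.asarray(doses, float)
    for d in np.sort(doses):
        if np.mean(doses >= d) <= p / 100.0 + 1e-12:
            return d
    return doses.max()


class TestDVH:
    def test_uniform_dose(self):
        mask = np.ones((4, 4, 1), bool)
        m = dvh_metrics(np.full((4, 4, 1), 50.0), mask)
        assert m.dmean == m.dmax == m.d2 == m.d98 == 50.0

    def test_two_voxel_example(self):
        dose = np.array([[[20.0, 60.0]]])
        m = dvh_metrics(dose, np.ones_like(dose, bool))
        assert m.dmean == 40.0 and m.dmax == 60.0

    def test_percentile_convention_1_to_100(self):
        dose = np.arange(1.0, 101.0).reshape(10, 10, 1)
        m = dvh_metrics(dose, np.ones_like(dose, bool))
        assert m.d98 == 3.0
        assert m.d2 == 99.0

    def test_empty_mask_not_evaluable(self):
        assert dvh_metrics(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool)) is None

    def test_curve_monotone_from_one_to_zero(self, rng):
        dose = 70 * rng.random((10, 10, 2))
        m = dvh_metrics(dose, np.ones_like(dose, bool))
        assert m.curve_volume_frac[0] == 1.0
        assert m.curve_volume_frac[-1] == 0.0
        assert np.all(np.diff(m.curve_volume_frac) <= 0)
        assert m.d2 >= m.d98 and m.dmean <= m.dmax

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.sampled_from([2.0, 50.0, 98.0]))
    def test_percentiles_match_brute_force_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        doses = np.round(80 * rng.random(rng.integers(1, 400)), 2)
        assert d_percent(doses, p) == brute_force_d_percent(doses, p)


class TestGEUD:
    def test_n1_is_mean(self, rng):
        dose = 70 * rng.random((8, 8, 4))
        mask = rng.random((8, 8, 4)) > 0.4
        assert geud(dose, mask, 1.0) == pytest.approx(dose[mask].mean(), rel=1e-14)

    def test_uniform_dose_any_n(self):
        dose = np.full((3, 3, 3), 35.0)
        mask = np.ones_like(dose, bool)
        for n in (0.2, 1.0, 3.0, -0.5):
            assert geud(dose, mask, n) == pytest.approx(35.0, rel=1e-12)

    def test_half_zero_half_sixty(self):
        dose = np.array([[[0.0, 60.0]]])
        assert geud(dose, np.ones_like(dose, bool), 1.0) == 30.0

    def test_all_zero_dose_returns_zero(self):
        dose = np.zeros((2, 2, 1))
        assert geud(dose, np.ones_like(dose, bool), -0.5) == 0.0

    def test_n_zero_rejected(self):
        with pytest.raises(DomainError):
            geud(np.ones((2, 2, 1)), np.ones((2, 2, 1), bool), 0.0)


class TestClosedForms:
    def test_logistic_midpoint_and_limits(self):
        assert ntcp_logistic_d50k(51.0, 51.0, 1.0) == pytest.approx(0.5, rel=1e-12)
        assert ntcp_logistic_d50k(0.0, 51.0, 1.0) == 0.0
        assert ntcp_logistic_d50k(102.0, 51.0, 1.0) == pytest.approx(2 / 3, rel=1e-12)

    def test_probit_midpoint_and_tails(self):
        assert ntcp_probit_geud(39.9, 39.9, 0.4) == pytest.approx(0.5, rel=1e-12)
        assert ntcp_probit_geud(39.9 * 1.4, 39.9, 0.4) == pytest.approx(
            norm.cdf(1.0), rel=1e-12
        )
        assert ntcp_probit_geud(0.0, 46.5, 0.5) == pytest.approx(
            norm.cdf(-2.0), rel=1e-12
        )

    def test_multivariable_logistic_values(self):
        assert ntcp_multivar_logistic(0.0, 0.0, 6.09, 0.057, 0.037) == pytest.approx(
            1.0 / (1.0 + math.exp(6.09)), rel=1e-12
        )
        x1_mid = (5.98 + 1.209) / 0.074
        assert ntcp_multivar_logistic(x1_mid, 1.0, 5.98, 0.074, -1.209) == pytest.approx(
            0.5, rel=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_outputs_in_unit_interval_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = sorted(rng.uniform(0, 120, 2))
        for f in (
            lambda d: ntcp_logistic_d50k(d, 51.0, 1.0),
            lambda d: ntcp_probit_geud(d, 39.9, 0.4),
            lambda d: ntcp_multivar_logistic(d, d, 6.09, 0.057, 0.037),
        ):
            lo, hi = f(d1), f(d2)
            assert 0.0 <= lo <= hi <= 1.0


ZERO_DOSE_NTCP = {
    "oral_mucositis": 0.0,
    "xerostomia": norm.cdf(-2.5),
    "swallow_solids": 1.0 / (1.0 + math.exp(5.98 + 1.209)),
    "swallow_liquids": 1.0 / (1.0 + math.exp(6.89)),
    "dysphagia": 1.0 / (1.0 + math.exp(6.09)),
    "aspiration": norm.cdf(-2.0),
}


class TestEvaluateAll:
    def test_zero_dose_closed_forms(self, tiny_patient):
        phantom, structures = tiny_patient
        result = evaluate_all(np.zeros(phantom.grid_shape), structures)
        for endpoint, expected in ZERO_DOSE_NTCP.items():
            assert result.values[endpoint] == pytest.approx(expected, rel=1e-12)

    def test_uniform_51_in_oral_mucosa_only(self, tiny_patient):
        phantom, structures = tiny_patient
        dose = np.zeros(phantom.grid_shape)
        dose[structures["ORAL_MUCOSA"]] = 51.0
        result = evaluate_all(dose, structures)
        assert result.values["oral_mucositis"] == pytest.approx(0.5, rel=1e-12)
        for endpoint in ("xerostomia", "aspiration"):
            assert result.values[endpoint] == pytest.approx(
                ZERO_DOSE_NTCP[endpoint], rel=1e-9
            )

    def test_missing_parotid_marks_xerostomia_not_evaluable(self, tiny_patient):
        from adaptntcp.anatomy import StructureSet

        phantom, structures = tiny_patient
        masks = {r: structures[r] for r in structures.roles if r != "PAROTID_CONTRA"}
        result = evaluate_all(np.zeros(phantom.grid_shape), StructureSet(masks))
        assert result.values["xerostomia"] is None
        assert "xerostomia" in result.not_evaluable
        assert result.values["aspiration"] == pytest.approx(
            ZERO_DOSE_NTCP["aspiration"], rel=1e-12
        )

    def test_engulfed_structure_not_evaluable(self, tiny_patient):
        from adaptntcp.anatomy import StructureSet

        phantom, structures = tiny_patient
        masks = dict(structures.masks)
        inside = np.zeros(phantom.grid_shape, bool)
        ctv = np.nonzero(masks["CTV_HIGH"])
        inside[ctv[0][0], ctv[1][0], ctv[2][0]] = True
        masks["LARYNX"] = inside  # larynx entirely within the boost volume
        result = evaluate_all(np.zeros(phantom.grid_shape), StructureSet(masks))
        assert result.values["aspiration"] is None
        assert "encompassed" in result.not_evaluable["aspiration"]

    def test_unknown_role_in_registry_rejected(self, tiny_patient):
        phantom, structures = tiny_patient
        registry = [NTCPModelSpec("bogus", "logistic_d50k", ["NOT_A_ROLE"],
                                  {"D50": 50.0, "k": 1.0})]
        with pytest.raises(ConfigurationError):
            evaluate_all(np.zeros(phantom.grid_shape), structures, registry)


def test_shipped_registry_matches_defaults():
    from adaptntcp.ntcp import shipped_registry_path

    shipped = registry_from_yaml(shipped_registry_path())
    defaults = default_registry()
    assert [(r.endpoint, r.family, r.structures, r.params) for r in shipped] == [
        (r.endpoint, r.family, r.structures, r.params) for r in defaults
    ]


def test_registry_yaml_round_trip(tmp_path):
    path = tmp_path / "registry.yaml"
    registry_to_yaml(default_registry(), path)
    loaded = registry_from_yaml(path)
    assert [r.endpoint for r in loaded] == [r.endpoint for r in default_registry()]
    assert all(
        a.params == b.params and a.structures == b.structures
        for a, b in zip(loaded, default_registry())
    )
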