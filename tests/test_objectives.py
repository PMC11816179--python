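import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

import intervalrt as irt
from intervalrt.interval_model import build_interval_model
from intervalrt.objectives import (
    Interval,
    ObjectiveSpec,
    PlanObjective,
    Prescription,
    bertoluzza_distance,
    f_ctv_interval,
    penalty,
)
from intervalrt.scenarios import ScenarioSet


class TestBertoluzzaMetric:
    def test_identity_and_radius_cancellation(self):
        assert bertoluzza_distance(Interval(5, 2), Interval(5, 2), 7) == 0.0
        assert bertoluzza_distance(Interval(3, 1), Interval(1, 1), 123.0) == pytest.approx(2.0)

    def test_sqrt_164_hand_example(self):
        d = bertoluzza_distance(Interval(80, 4), Interval(78, 0), theta=10.0)
        assert d == pytest.approx(np.sqrt(164.0), rel=1e-12)

    def test_negative_theta_raises(self):
        with pytest.raises(ValueError):
            bertoluzza_distance(Interval(1, 0), Interval(2, 0), -1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.floats(-50, 150) for _ in range(3)]),
        st.tuples(*[st.floats(0, 30) for _ in range(3)]),
        st.floats(1e-3, 100),
    )
    def test_metric_axioms(self, centers, radii, theta):
        X, Y, Z = (Interval(c, r) for c, r in zip(centers, radii))
        dxy = bertoluzza_distance(X, Y, theta)
        assert dxy == pytest.approx(bertoluzza_distance(Y, X, theta), rel=1e-12)
        assert bertoluzza_distance(X, X, theta) == 0.0
        dxz = bertoluzza_distance(X, Z, theta)
        dzy = bertoluzza_distance(Z, Y, theta)
        assert dxy <= dxz + dzy + 1e-9


class TestPenalties:
    def test_squared_overdose_hand_case(self):
        spec = ObjectiveSpec("s", "SqOver", 39.0, 1.0)
        val, grad = penalty(np.array([30.0, 40.0]), spec, np.array([True, True]))
        assert val == pytest.approx(0.5)
        np.testing.assert_allclose(grad, [0.0, 1.0])

    def test_dose_min_satisfied_is_zero(self):
        spec = ObjectiveSpec("s", "DoseMin", 78.0, 1.0)
        val, _ = penalty(np.array([78.0, 90.0, 78.5]), spec, np.ones(3, bool))
        assert val == 0.0

    def test_max_dvh_inactive_when_constraint_met(self):
        # V81Gy = 3% < 5%: no violating voxels to push
        d = np.full(100, 70.0)
        d[:3] = 82.0
        spec = ObjectiveSpec("s", "MaxDVH", 81.0, 1.0, volume_fraction=0.05)
        val, grad = penalty(d, spec, np.ones(100, bool))
        assert val == 0.0
        assert not grad.any()

    def test_max_dvh_pushes_coldest_violators_only(self):
        # 40% of voxels exceed 60 Gy but only 20% are allowed: the hottest
        # 20% are spared, the remaining violators are penalized
        d = np.array([50.0, 55.0, 61.0, 62.0, 70.0, 80.0, 30.0, 20.0, 40.0, 45.0])
        spec = ObjectiveSpec("s", "MaxDVH", 60.0, 1.0, volume_fraction=0.2)
        val, grad = penalty(d, spec, np.ones(10, bool))
        assert val == pytest.approx((1.0**2 + 2.0**2) / 10)
        assert grad[4] == 0.0 and grad[5] == 0.0  # hottest fraction untouched
        assert grad[2] > 0 and grad[3] > 0

    def test_unknown_type_rejected_at_spec_construction(self):
        with pytest.raises(ValueError, match="unknown penalty type"):
            ObjectiveSpec("s", "MeanDose", 50.0, 1.0)

    def test_empty_mask_raises(self):
        spec = ObjectiveSpec("s", "SqDev", 78.0, 1.0)
        with pytest.raises(ValueError):
            penalty(np.ones(4), spec, np.zeros(4, bool))


def toy_interval_model(center_doses, weights=None):
    """Interval model over single-bixel scenario matrices (n voxels, m=1)."""
    Dks = [sparse.csr_matrix(np.asarray(d, float).reshape(-1, 1)) for d in center_doses]
    K = len(Dks)
    w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights)
    shifts = np.zeros((K, 3))
    sset = ScenarioSet(shifts, w, nominal_index=0, tag="optimization")
    return build_interval_model(Dks, sset, variance_threshold=1.0)


class TestCtvIntervalObjective:
    def test_perfect_dose_and_zero_radius_scores_zero(self):
        model = toy_interval_model([[78.0, 78.0], [78.0, 78.0]])
        val, grad = f_ctv_interval(
            np.ones(1), model, np.ones(2, bool), Prescription(78.0), theta=5.0
        )
        assert val == pytest.approx(0.0, abs=1e-18)

    def test_hand_arithmetic_center_and_radius(self):
        # one CTV voxel: scenarios 79 and 81 Gy -> center 80, radius 1
        model = toy_interval_model([[79.0], [81.0]])
        val, _ = f_ctv_interval(np.ones(1), model, np.ones(1, bool), Prescription(78.0), 1.0)
        assert val == pytest.approx((80 - 78) ** 2 + 1.0)

    def test_theta_zero_reduces_to_center_deviation(self):
        model = toy_interval_model([[70.0, 90.0], [74.0, 80.0]])
        val, _ = f_ctv_interval(np.ones(1), model, np.ones(2, bool), Prescription(78.0), 0.0)
        dc = model.center_dose(np.ones(1))
        assert val == pytest.approx(np.sum((dc - 78.0) ** 2))

    def test_empty_ctv_raises(self):
        model = toy_interval_model([[78.0], [78.0]])
        with pytest.raises(ValueError, match="empty CTV"):
            f_ctv_interval(np.ones(1), model, np.zeros(1, bool), Prescription(78.0), 1.0)


class TestCompositeObjectives:
    def test_interval_mode_with_zero_oar_weights_is_pure_ctv_term(self):
        model = toy_interval_model([[70.0, 75.0], [80.0, 85.0]])
        masks = {"CTV": np.ones(2, bool), "body": np.ones(2, bool)}
        specs = [
            ObjectiveSpec("CTV", "DoseMin", 78.0, 0.0),
            ObjectiveSpec("body", "SqOver", 39.0, 0.0),
        ]
        obj = PlanObjective(
            "interval", specs, masks, interval=model,
            prescription=Prescription(78.0), theta=2.0, omega_ctv=0.7,
        )
        x = np.array([1.0])
        expect, _ = f_ctv_interval(x, model, masks["CTV"], Prescription(78.0), 2.0)
        assert obj.value(x) == pytest.approx(0.7 * expect)

    def test_minimax_single_scenario_equals_nominal(self):
        D = sparse.csr_matrix(np.array([[60.0], [80.0]]))
        masks = {"CTV": np.array([True, True])}
        specs = [ObjectiveSpec("CTV", "SqDev", 78.0, 1.0)]
        x = np.array([1.0])
        nom = PlanObjective("nominal", specs, masks, nominal=D)
        mm = PlanObjective("minimax", specs, masks, scenario_matrices=[D])
        assert mm.value(x) == pytest.approx(nom.value(x))

    def test_smoothed_max_respects_log_sum_exp_bound(self):
        # composites 3 and 7: hard max 7, smoothed within log(2)/beta above
        D1 = sparse.csr_matrix([[np.sqrt(3.0)]])
        D2 = sparse.csr_matrix([[np.sqrt(7.0)]])
        masks = {"CTV": np.array([True])}
        specs = [ObjectiveSpec("CTV", "SqDev", 0.0, 1.0)]
        beta = 10.0
        hard = PlanObjective("minimax", specs, masks, scenario_matrices=[D1, D2],
                             smooth_max=False)
        smooth = PlanObjective("minimax", specs, masks, scenario_matrices=[D1, D2],
                               beta=beta)
        x = np.array([1.0])
        assert hard.value(x) == pytest.approx(7.0)
        assert 7.0 <= smooth.value(x) <= 7.0 + np.log(2) / beta

    def test_ptv_mode_requires_ptv_mask(self):
        D = sparse.csr_matrix([[70.0]])
        with pytest.raises(ValueError, match="PTV"):
            PlanObjective("ptv", [], {"CTV": np.array([True])}, nominal=D)

    def test_theta_monotonicity_at_fixed_fluence(self, small_workspace):
        ws = small_workspace
        x = irt.initial_fluence(ws.interval.center, ws.masks("interval")["CTV"], 78.0)
        vals = [ws.objective("interval", theta=t).value(x) for t in (0, 0.5, 1, 2, 5, 10)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_upper_bound_penalties_dominate_center_penalties(self, small_workspace):
        """Scoring OARs on dbar = center + radius is conservative."""
        ws = small_workspace
        masks = ws.masks("interval")
        x = irt.initial_fluence(ws.interval.center, masks["CTV"], 78.0)
        dc = ws.interval.center_dose(x)
        dbar = ws.interval.upper(x)
        for spec in ws.specs:
            if spec.kind in ("DoseMax", "SqOver") and not spec.ptv_only:
                v_up, _ = penalty(dbar, spec, masks[spec.structure])
                v_c, _ = penalty(dc, spec, masks[spec.structure])
                assert v_up >= v_c - 1e-12


class TestGradients:
    @pytest.mark.parametrize("mode", ["nominal", "ptv", "minimax", "interval"])
    def test_analytic_gradients_match_central_differences(self, small_workspace, mode):
        ws = small_workspace
        obj = ws.objective(mode)
        masks = ws.masks(mode)
        x0 = irt.initial_fluence(ws.interval.center, masks["CTV"], 78.0)
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = x0 * (0.5 + rng.random(x0.size))
            _, g = obj.value_and_grad(x)
            fd = np.empty_like(g)
            for j in range(x.size):
                h = 1e-6 * (1.0 + abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                fd[j] = (obj.value(xp) - obj.value(xm)) / (2 * h)
            assert np.linalg.norm(g - fd) <= 1e-5 * max(np.linalg.norm(fd), 1.0)
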