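"""CRIP / MDAR / GRIP formulas, stability and interobserver reliability."""

import math

import numpy as np
import pytest

from gripcalc import (
    DomainError,
    HerniaGeometry,
    MeshPlan,
    ObserverReadings,
    ProtocolError,
    UndersizedMeshWarning,
    classify_stability,
    crip,
    defect_size,
    grip,
    interobserver_check,
    mdar,
)
from gripcalc.registry_model import CoefficientTable, FixationBand


def make_plan(width, length, **kw):
    defaults = dict(
        mesh_width=width,
        mesh_length=length,
        minimal_overlap=5,
        fixation_points=0,
        fixation_type="none",
    )
    defaults.update(kw)
    return MeshPlan(**defaults)


class TestDefectSize:
    def test_ellipse_area_of_4_by_6(self):
        assert defect_size(4, 6) == pytest.approx(18.85, abs=0.005)

    def test_symmetric_case_scales_quadratically(self):
        for d in (1.0, 3.7, 12.0):
            assert defect_size(d, d) == pytest.approx(math.pi / 4 * d * d)
            assert defect_size(2 * d, 2 * d) == pytest.approx(4 * defect_size(d, d))

    def test_ellipse_is_pi_over_4_of_rectangle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            w, l = rng.uniform(0.5, 40, size=2)
            assert defect_size(w, l) / (w * l) == pytest.approx(math.pi / 4)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(DomainError):
            defect_size(0, 5)
        with pytest.raises(DomainError):
            defect_size(4, -1)


class TestCrip:
    @pytest.mark.parametrize(
        "size,distension,expected",
        [(0, 1.0, 15.0), (100, 2.0, 130.0), (430, 1.0, 230.0)],
    )
    def test_direct_formula(self, size, distension, expected):
        assert crip(size, distension) == pytest.approx(expected)

    def test_closed_form_limits(self):
        for d in (0.1, 1.5, 7.0):
            assert crip(0, d) == pytest.approx(15 * d)
        for s in (0.0, 50.0, 430.0):
            assert crip(s, 0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            crip(-1, 1)
        with pytest.raises(DomainError):
            crip(10, -0.1)


class TestMdar:
    def test_direct_ratio(self):
        geom = HerniaGeometry(4, 6, 1.0)
        assert mdar(make_plan(15, 20), geom) == pytest.approx(12.5)

    def test_identity_when_mesh_equals_defect(self):
        geom = HerniaGeometry(7, 9, 1.0)
        assert mdar(make_plan(7, 9), geom) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        geom = HerniaGeometry(4, 6, 1.0)
        base = mdar(make_plan(15, 20), geom)
        for _ in range(1000):
            k = rng.uniform(0.1, 10)
            scaled = mdar(make_plan(15 * k, 20 * k), HerniaGeometry(4 * k, 6 * k, 1.0))
            assert scaled == pytest.approx(base)

    def test_undersized_mesh_warns_but_scores(self):
        geom = HerniaGeometry(10, 10, 1.0)
        with pytest.warns(UndersizedMeshWarning):
            ratio = mdar(make_plan(8, 12), geom)
        assert ratio == pytest.approx(0.96)


class TestGrip:
    def test_identity_table_reduces_to_mdar(self, identity_coeffs):
        plan = make_plan(15, 20)
        assert grip(12.5, plan, identity_coeffs) == pytest.approx(12.5)

    def test_fixation_and_closure_terms(self):
        table = CoefficientTable(
            adhesiveness={"dis_class_a": 1.0},
            position={"retromuscular": 1.0},
            fixation={"nonresorbable_suture": (FixationBand(up_to=None, multiplier=2.0),)},
            peritoneal_closure_factor=0.0,
            fascial_closure_factor=10.0,
        )
        plan = make_plan(
            10, 10, fixation_points=12, fixation_type="nonresorbable_suture",
            fascial_closure=True,
        )
        assert grip(5.0, plan, table) == pytest.approx(20.0)

    def test_strictly_increasing_in_mdar_for_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            table = CoefficientTable(
                adhesiveness={"dis_class_a": rng.uniform(0.1, 5)},
                position={"retromuscular": rng.uniform(0.1, 5)},
                fixation={
                    "nonresorbable_suture": (
                        FixationBand(up_to=None, multiplier=float(rng.uniform(0.1, 5))),
                    )
                },
                peritoneal_closure_factor=float(rng.uniform(0, 20)),
                fascial_closure_factor=float(rng.uniform(0, 20)),
            )
            plan = make_plan(
                10, 10, fixation_points=int(rng.integers(1, 200)),
                fixation_type="nonresorbable_suture",
                peritoneal_closure=bool(rng.integers(2)),
                fascial_closure=bool(rng.integers(2)),
            )
            m1, m2 = sorted(rng.uniform(0, 40, size=2))
            if m1 == m2:
                continue
            assert grip(m1, plan, table) < grip(m2, plan, table)


class TestStability:
    @pytest.mark.parametrize(
        "distension,expected",
        [(0.0, "stable"), (1.5, "stable"), (1.6, "unstable"), (10.0, "unstable")],
    )
    def test_boundary_inclusive_at_1_5_cm(self, distension, expected):
        assert classify_stability(distension) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            classify_stability(-0.1)


class TestInterobserver:
    def _with_cv(self, target_cv: float) -> ObserverReadings:
        """Readings whose pooled cv is within float error of ``target_cv``."""
        base = np.array(
            [
                [20.0, 21.0, 19.5, 20.5],
                [20.2, 19.8, 20.4, 19.6],
                [21.0, 19.0, 20.1, 19.9],
            ]
        )
        flat = base.ravel()
        mean, sd = flat.mean(), flat.std(ddof=1)
        scaled = mean + (base - mean) * (target_cv * mean / sd)
        return ObserverReadings(scaled)

    def test_identical_readings_are_reliable(self):
        readings = ObserverReadings(np.full((3, 4), 12.5))
        result = interobserver_check(readings)
        assert result.cv == 0.0 and result.reliable

    def test_recurrence_level_variation_is_unreliable(self):
        """18% interobserver variation — the level seen in the one failed
        measurement protocol — must be flagged unreliable."""
        result = interobserver_check(self._with_cv(0.18))
        assert result.cv == pytest.approx(0.18)
        assert not result.reliable

    def test_threshold_is_strict_at_5_percent(self):
        assert not interobserver_check(self._with_cv(0.0500001)).reliable
        assert interobserver_check(self._with_cv(0.0499999)).reliable

    def test_protocol_minimums_enforced(self):
        with pytest.raises(ProtocolError):
            ObserverReadings(np.full((2, 4), 10.0))
        with pytest.raises(ProtocolError):
            ObserverReadings(np.full((3, 3), 10.0))
        with pytest.raises(ProtocolError):
            ObserverReadings(np.array([[1.0, 2, 3, 0], [1, 2, 3, 4], [1, 2, 3, 4]]))

    def test_cv_is_permutation_and_scale_invariant(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(15, 25, size=(4, 5))
        cv0 = interobserver_check(ObserverReadings(base)).cv
        shuffled = base.ravel()
        rng.shuffle(shuffled)
        assert interobserver_check(ObserverReadings(shuffled.reshape(4, 5))).cv == pytest.approx(cv0)
        assert interobserver_check(ObserverReadings(base * 3.7)).cv == pytest.approx(cv0)
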