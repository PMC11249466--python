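"""Repair planner: minimality, determinism and the escalation walk."""

import numpy as np
import pytest

from gripcalc import (
    HerniaGeometry,
    InfeasibleRepairError,
    PlannerConstraints,
    assess,
    escalation_trace,
    plan_repair,
)
from gripcalc.repair_planner import _state_to_plan  # noqa: F401  (not used by oracle)


def oracle_states(geom, c: PlannerConstraints):
    """Independent enumeration of the escalation walk as raw tuples
    (overlap, points, type, peritoneal, fascial)."""
    room = min(
        (c.max_mesh_width - geom.defect_width) / 2,
        (c.max_mesh_length - geom.defect_length) / 2,
    )
    if room < c.min_overlap:
        overlaps = [max(0.0, room)]
    else:
        overlaps = []
        o = c.min_overlap
        while o <= room + 1e-9:
            overlaps.append(o)
            o += c.overlap_step
    states = [(o, 0, "none", False, False) for o in overlaps]
    o_max = overlaps[-1]
    points = list(range(c.fixation_step, c.max_fixation_points + 1, c.fixation_step))
    states += [(o_max, p, c.allowed_fixation_types[0], False, False) for p in points]
    p_max = points[-1] if points else 0
    if points:
        states += [(o_max, p_max, t, False, False) for t in c.allowed_fixation_types[1:]]
    t_last = c.allowed_fixation_types[-1] if points else "none"
    if c.allow_peritoneal_closure:
        states.append((o_max, p_max, t_last, True, False))
    if c.allow_fascial_closure:
        states.append((o_max, p_max, t_last, c.allow_peritoneal_closure, True))
    return states


def oracle_grip(state, geom, coeffs, c):
    o, points, ftype, perit, fasc = state
    ratio = ((geom.defect_width + 2 * o) * (geom.defect_length + 2 * o)) / (
        geom.defect_width * geom.defect_length
    )
    value = (
        ratio
        * coeffs.adhesiveness_for(c.adhesiveness_class)
        * coeffs.position_for(c.position_class)
        * coeffs.fixation_for(ftype, points)
    )
    if perit:
        value += coeffs.peritoneal_closure_factor
    if fasc:
        value += coeffs.fascial_closure_factor
    return value


def oracle_plan(geom, coeffs, c: PlannerConstraints):
    """Exhaustive search: first durable state in escalation order, else None."""
    from gripcalc import crip, defect_size

    required = crip(defect_size(geom.defect_width, geom.defect_length), geom.distension)
    for state in oracle_states(geom, c):
        if oracle_grip(state, geom, coeffs, c) > required:
            return state
    return None


def plan_as_state(plan):
    return (
        plan.minimal_overlap,
        plan.fixation_points,
        plan.fixation_type,
        plan.peritoneal_closure,
        plan.fascial_closure,
    )


def test_minimal_plan_for_small_defect(identity_coeffs):
    """Defect 4x6 cm at 1 cm distension: CRIP 24.42; with identity
    coefficients the planner must return the smallest walk plan whose
    MDAR exceeds it (overlap 10 cm, mesh 24x26)."""
    geom = HerniaGeometry(4, 6, 1.0)
    plan, result = plan_repair(geom, identity_coeffs)
    assert result.crip == pytest.approx(24.42, abs=0.005)
    assert (plan.mesh_width, plan.mesh_length) == (24.0, 26.0)
    assert result.mdar == pytest.approx(26.0)
    assert result.durable and result.grip > result.crip


def test_zero_distension_needs_no_escalation(identity_coeffs):
    geom = HerniaGeometry(4, 6, 0.0)
    plan, result = plan_repair(geom, identity_coeffs)
    assert result.crip == 0.0
    assert plan.minimal_overlap == PlannerConstraints().min_overlap
    assert plan.fixation_points == 0
    trace = escalation_trace(geom, identity_coeffs)
    assert len(trace) == 1 and trace[0][1].durable


def test_giant_defect_is_infeasible_with_reported_margin(identity_coeffs):
    geom = HerniaGeometry(30, 40, 10.0)
    with pytest.raises(InfeasibleRepairError) as exc:
        plan_repair(geom, identity_coeffs)
    assert exc.value.margin < 0
    assert oracle_plan(geom, identity_coeffs, PlannerConstraints()) is None
    # best achievable margin agrees with the exhaustive search
    c = PlannerConstraints()
    from gripcalc import crip, defect_size

    required = crip(defect_size(30, 40), 10.0)
    best = max(
        oracle_grip(s, geom, identity_coeffs, c) - required
        for s in oracle_states(geom, c)
    )
    assert exc.value.margin == pytest.approx(best)


@pytest.mark.parametrize("table", ["identity_coeffs", "example_coeffs"])
def test_planner_matches_exhaustive_oracle_on_random_geometries(table, request):
    """100 random geometries: identical plan or identical infeasibility."""
    coeffs = request.getfixturevalue(table)
    c = PlannerConstraints()
    rng = np.random.default_rng(11)
    n_feasible = 0
    for _ in range(100):
        geom = HerniaGeometry(
            defect_width=float(rng.uniform(2, 30)),
            defect_length=float(rng.uniform(2, 40)),
            distension=float(rng.uniform(0, 4)),
        )
        expected = oracle_plan(geom, coeffs, c)
        if expected is None:
            with pytest.raises(InfeasibleRepairError):
                plan_repair(geom, coeffs, c)
        else:
            plan, result = plan_repair(geom, coeffs, c)
            assert plan_as_state(plan) == expected
            assert result.durable and result.grip > result.crip
            n_feasible += 1
    assert n_feasible > 0


def _one_escalation_step(prev, cur):
    """True iff cur differs from prev by exactly one escalation move:
    overlap up, fixation points up (the first increment also selects the
    first fixation type), fixation type advanced, or one closure toggled."""
    overlap_up = cur.minimal_overlap > prev.minimal_overlap
    points_up = cur.fixation_points > prev.fixation_points
    type_change = cur.fixation_type != prev.fixation_type
    perit_on = cur.peritoneal_closure and not prev.peritoneal_closure
    fasc_on = cur.fascial_closure and not prev.fascial_closure
    same_closures = not perit_on and not fasc_on
    if overlap_up:
        return not points_up and not type_change and same_closures
    if points_up:
        if prev.fixation_points == 0:
            return same_closures  # type 'none' -> first allowed type
        return not type_change and same_closures
    if type_change:
        return prev.fixation_points > 0 and same_closures
    return (perit_on != fasc_on) and cur.minimal_overlap == prev.minimal_overlap


def test_trace_structure_and_consistency(example_coeffs):
    """Traces are single-step walks with non-decreasing GRIP ending at the
    plan the planner returns (or marked infeasible)."""
    c = PlannerConstraints()
    rng = np.random.default_rng(12)
    for _ in range(100):
        geom = HerniaGeometry(
            defect_width=float(rng.uniform(2, 30)),
            defect_length=float(rng.uniform(2, 40)),
            distension=float(rng.uniform(0, 4)),
        )
        trace = escalation_trace(geom, example_coeffs, c)
        grips = [a.grip for _, a in trace]
        assert all(g2 >= g1 - 1e-9 for g1, g2 in zip(grips, grips[1:]))
        for (p1, _), (p2, _) in zip(trace, trace[1:]):
            assert _one_escalation_step(p1, p2)
        if trace[-1][1].durable:
            plan, result = plan_repair(geom, example_coeffs, c)
            assert plan == trace[-1][0]
            assert all(not a.durable for _, a in trace[:-1])
        else:
            with pytest.raises(InfeasibleRepairError):
                plan_repair(geom, example_coeffs, c)


def test_more_distension_never_shrinks_the_mesh(example_coeffs):
    """Monotone resource use: raising distension cannot reduce mesh area."""
    rng = np.random.default_rng(13)
    c = PlannerConstraints()
    for _ in range(50):
        w = float(rng.uniform(2, 20))
        l = float(rng.uniform(2, 25))
        d1 = float(rng.uniform(0, 2))
        d2 = d1 + float(rng.uniform(0.1, 2))
        try:
            p1, _ = plan_repair(HerniaGeometry(w, l, d1), example_coeffs, c)
            p2, _ = plan_repair(HerniaGeometry(w, l, d2), example_coeffs, c)
        except InfeasibleRepairError:
            continue
        assert p2.mesh_width * p2.mesh_length >= p1.mesh_width * p1.mesh_length


def test_planner_is_deterministic(example_coeffs):
    geom = HerniaGeometry(12, 18, 1.4)
    first = plan_repair(geom, example_coeffs)
    second = plan_repair(geom, example_coeffs)
    assert first[0] == second[0] and first[1] == second[1]
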