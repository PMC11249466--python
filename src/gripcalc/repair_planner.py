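"""Iterative repair planning: escalate the plan until GRIP exceeds CRIP.

The clinical loop designs a repair, computes its gained resistance (GRIP) and
compares it with the required resistance (CRIP); if the repair is not durable
it is escalated and re-assessed. Here the escalation is a deterministic,
monotone walk through a discrete plan grid:

1. enlarge the mesh — overlap grows in ``overlap_step`` increments from
   ``min_overlap`` up to the mesh-size caps (mesh = defect + 2 x overlap,
   isotropic);
2. add fixation — fixation points grow in ``fixation_step`` increments up to
   ``max_fixation_points`` (the first increment selects the first allowed
   fixation type);
3. strengthen fixation — advance along the ordered ``allowed_fixation_types``
   escalation list;
4. switch on the closure factors — peritoneal, then fascial.

``plan_repair`` returns the first durable state on this walk, i.e. the
minimal plan under the escalation order; ``escalation_trace`` returns the
audited walk itself. The order (larger meshes before more fixation before
closure) mirrors clinical practice — larger hernias get larger meshes first,
then the number of fixation points is increased — and is configurable through
the constraint object. GRIP is non-decreasing along the walk whenever the
coefficient table is escalation-monotone (band multipliers non-decreasing in
points, type multipliers non-decreasing along the escalation list).
"""

from __future__ import annotations

from typing import Iterator, NamedTuple

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .biomech_scores import HerniaGeometry, RepairAssessment, assess, crip
from .errors import InfeasibleRepairError
from .registry_model import CoefficientTable, MeshPlan


class PlannerConstraints(BaseModel):
    """Bounds and step sizes of the escalation grid.

    Mesh caps default to 49 x 49 cm (largest meshes on the market); minimal
    overlap defaults to the conventional 5 cm. When the caps leave less than
    ``min_overlap`` of room, the planner degrades to the largest overlap the
    caps allow (never below zero) rather than failing outright.
    """

    model_config = ConfigDict(frozen=True)

    max_mesh_width: float = Field(default=49.0, gt=0)
    max_mesh_length: float = Field(default=49.0, gt=0)
    min_overlap: float = Field(default=5.0, ge=0)
    overlap_step: float = Field(default=0.5, gt=0)
    fixation_step: int = Field(default=10, gt=0)
    max_fixation_points: int = Field(default=300, ge=0)
    allowed_fixation_types: tuple[str, ...] = (
        "absorbable_tack",
        "nonresorbable_suture",
        "pull_out_suture",
        "bone_anchor",
    )
    allow_peritoneal_closure: bool = True
    allow_fascial_closure: bool = True
    adhesiveness_class: str = "dis_class_a"
    position_class: str = "retromuscular"
    mesh_form: str = "flat_mesh"

    @field_validator("allowed_fixation_types")
    @classmethod
    def _nonempty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("allowed_fixation_types must not be empty")
        return v


class _State(NamedTuple):
    overlap: float
    points: int
    fixation_type: str
    peritoneal: bool
    fascial: bool


def _overlap_grid(geom: HerniaGeometry, c: PlannerConstraints) -> list[float]:
    room = min(
        (c.max_mesh_width - geom.defect_width) / 2.0,
        (c.max_mesh_length - geom.defect_length) / 2.0,
    )
    if room < c.min_overlap:
        return [max(0.0, room)]
    n = int((room - c.min_overlap) / c.overlap_step + 1e-9)
    return [c.min_overlap + k * c.overlap_step for k in range(n + 1)]


def _walk(geom: HerniaGeometry, c: PlannerConstraints) -> Iterator[_State]:
    overlaps = _overlap_grid(geom, c)
    for o in overlaps:
        yield _State(o, 0, "none", False, False)
    o_max = overlaps[-1]
    points_grid = list(range(c.fixation_step, c.max_fixation_points + 1, c.fixation_step))
    first_type = c.allowed_fixation_types[0]
    for p in points_grid:
        yield _State(o_max, p, first_type, False, False)
    p_max = points_grid[-1] if points_grid else 0
    if points_grid:
        for t in c.allowed_fixation_types[1:]:
            yield _State(o_max, p_max, t, False, False)
    last_type = c.allowed_fixation_types[-1] if points_grid else "none"
    if c.allow_peritoneal_closure:
        yield _State(o_max, p_max, last_type, True, False)
    if c.allow_fascial_closure:
        yield _State(o_max, p_max, last_type, c.allow_peritoneal_closure, True)


def _state_to_plan(state: _State, geom: HerniaGeometry, c: PlannerConstraints) -> MeshPlan:
    return MeshPlan(
        mesh_width=geom.defect_width + 2 * state.overlap,
        mesh_length=geom.defect_length + 2 * state.overlap,
        minimal_overlap=state.overlap,
        mesh_form=c.mesh_form,
        adhesiveness_class=c.adhesiveness_class,
        position_class=c.position_class,
        fixation_points=state.points,
        fixation_type=state.fixation_type,
        peritoneal_closure=state.peritoneal,
        fascial_closure=state.fascial,
    )


def _state_grip(
    state: _State, geom: HerniaGeometry, coeffs: CoefficientTable, base_mult: float
) -> float:
    mesh_area = (geom.defect_width + 2 * state.overlap) * (
        geom.defect_length + 2 * state.overlap
    )
    ratio = mesh_area / (geom.defect_width * geom.defect_length)
    value = ratio * base_mult * coeffs.fixation_for(state.fixation_type, state.points)
    if state.peritoneal:
        value += coeffs.peritoneal_closure_factor
    if state.fascial:
        value += coeffs.fascial_closure_factor
    return value


def plan_repair(
    geom: HerniaGeometry,
    coeffs: CoefficientTable,
    constraints: PlannerConstraints | None = None,
) -> tuple[MeshPlan, RepairAssessment]:
    """Find the minimal escalation achieving GRIP > CRIP.

    Deterministic for fixed inputs: returns the first durable state of the
    escalation walk. Raises :class:`InfeasibleRepairError` (carrying the best
    achievable plan and margin) when no grid state is durable.
    """
    c = constraints or PlannerConstraints()
    required = crip(geom.defect_size, geom.distension)
    base_mult = coeffs.adhesiveness_for(c.adhesiveness_class) * coeffs.position_for(
        c.position_class
    )
    best_state: _State | None = None
    best_margin = -float("inf")
    for state in _walk(geom, c):
        margin = _state_grip(state, geom, coeffs, base_mult) - required
        if margin > 0:
            plan = _state_to_plan(state, geom, c)
            return plan, assess(geom, plan, coeffs)
        if margin > best_margin:
            best_margin = margin
            best_state = state
    assert best_state is not None
    best_plan = _state_to_plan(best_state, geom, c)
    raise InfeasibleRepairError(best_plan, assess(geom, best_plan, coeffs), best_margin)


def escalation_trace(
    geom: HerniaGeometry,
    coeffs: CoefficientTable,
    constraints: PlannerConstraints | None = None,
) -> list[tuple[MeshPlan, RepairAssessment]]:
    """The audited escalation walk, stopping at the first durable state.

    If no state is durable the full walk is returned and the last element's
    assessment is not durable; callers detect infeasibility from
    ``trace[-1][1].durable``.
    """
    c = constraints or PlannerConstraints()
    trace: list[tuple[MeshPlan, RepairAssessment]] = []
    for state in _walk(geom, c):
        plan = _state_to_plan(state, geom, c)
        result = assess(geom, plan, coeffs)
        trace.append((plan, result))
        if result.durable:
            break
    return trace
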