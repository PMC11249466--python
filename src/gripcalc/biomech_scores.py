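"""CRIP, MDAR and GRIP: the biomechanical scores of calculated hernia repair.

The required strength of a repair is the Critical Resistance to Impacts
related to Pressure,

    CRIP = (0.5 * hernia size + 15) * tissue distension,

where "hernia size" is taken as the elliptical defect area in cm^2
(``pi/4 * width * length``) and distension is the maximum abdominal-wall
displacement (cm) under a Valsalva maneuver. The achieved strength is the
Gained Resistance to Impacts related to Pressure,

    GRIP = MDAR * c_adhesiveness * c_position * c_fixation(type, points)
           + f_peritoneal * [peritoneal closure] + f_fascial * [fascial closure],

with MDAR the mesh-defect area ratio (mesh area / defect area; the elliptical
constant cancels). A repair is durable when GRIP > CRIP (strict). CRIP and
GRIP are dimensionless resistance scores.

Tissue is classified stable when the Valsalva distension does not exceed
1.5 cm. Manual hernia measurements are reliable when the pooled coefficient
of variation of at least three observers' readings (four or more each) stays
below 5%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .errors import DomainError, ProtocolError, UndersizedMeshWarning
from .registry_model import CoefficientTable, MeshPlan

STABILITY_LIMIT_CM = 1.5
INTEROBSERVER_CV_LIMIT = 0.05


@dataclass(frozen=True)
class HerniaGeometry:
    """Defect geometry and loading: width/length (cm), Valsalva distension (cm),
    optionally the unstable wall area (cm^2) from an instability map."""

    defect_width: float
    defect_length: float
    distension: float
    unstable_area: Optional[float] = None

    def __post_init__(self) -> None:
        if self.defect_width <= 0 or self.defect_length <= 0:
            raise DomainError("defect dimensions must be positive")
        if self.distension < 0:
            raise DomainError("distension must be >= 0")

    @property
    def defect_size(self) -> float:
        """Elliptical defect area in cm^2."""
        return defect_size(self.defect_width, self.defect_length)


@dataclass(frozen=True)
class RepairAssessment:
    """CRIP/GRIP verdict for one (geometry, mesh plan) pair."""

    crip: float
    grip: float
    mdar: float
    stable_tissue: bool
    margin: float
    durable: bool


def defect_size(width: float, length: float) -> float:
    """Elliptical defect area ``pi/4 * width * length`` in cm^2.

    The ellipse is the conventional model for a hernia orifice measured by
    its two principal diameters; the convention is isolated here so it can be
    swapped wholesale.
    """
    if width <= 0 or length <= 0:
        raise DomainError("width and length must be positive")
    return math.pi / 4.0 * width * length


def crip(size: float, distension: float) -> float:
    """Critical resistance: ``(0.5 * size + 15) * distension``.

    ``size`` is the defect area in cm^2, ``distension`` the maximum Valsalva
    displacement in cm. Strictly increasing in either argument when the other
    is positive; zero distension means zero required resistance.
    """
    if size < 0 or distension < 0:
        raise DomainError("size and distension must be >= 0")
    return (0.5 * size + 15.0) * distension


def mdar(plan: MeshPlan, geom: HerniaGeometry) -> float:
    """Mesh-defect area ratio: mesh area / defect area.

    Shape-model independent as long as mesh and defect share one (the
    elliptical constants cancel). A mesh smaller than the defect in either
    dimension raises :class:`UndersizedMeshWarning` but is still scored.
    """
    if plan.mesh_width < geom.defect_width or plan.mesh_length < geom.defect_length:
        warnings.warn(
            "mesh smaller than defect in at least one dimension",
            UndersizedMeshWarning,
            stacklevel=2,
        )
    return (plan.mesh_width * plan.mesh_length) / (geom.defect_width * geom.defect_length)


def grip(mdar_value: float, plan: MeshPlan, coeffs: CoefficientTable) -> float:
    """Gained resistance for a plan at a given mesh-defect area ratio.

    Multiplicative chain (adhesiveness x position x fixation) applied to the
    MDAR, then the additive closure factors. Missing coefficient lookups are
    config errors.
    """
    if mdar_value < 0:
        raise DomainError("mdar must be >= 0")
    value = (
        mdar_value
        * coeffs.adhesiveness_for(plan.adhesiveness_class)
        * coeffs.position_for(plan.position_class)
        * coeffs.fixation_for(plan.fixation_type, plan.fixation_points)
    )
    if plan.peritoneal_closure:
        value += coeffs.peritoneal_closure_factor
    if plan.fascial_closure:
        value += coeffs.fascial_closure_factor
    return value


def classify_stability(distension: float) -> Literal["stable", "unstable"]:
    """Stable tissue iff Valsalva distension <= 1.5 cm (boundary inclusive)."""
    if distension < 0:
        raise DomainError("distension must be >= 0")
    return "stable" if distension <= STABILITY_LIMIT_CM else "unstable"


def assess(geom: HerniaGeometry, plan: MeshPlan, coeffs: CoefficientTable) -> RepairAssessment:
    """Full CRIP/MDAR/GRIP assessment of a planned repair."""
    ratio = mdar(plan, geom)
    required = crip(geom.defect_size, geom.distension)
    gained = grip(ratio, plan, coeffs)
    margin = gained - required
    return RepairAssessment(
        crip=required,
        grip=gained,
        mdar=ratio,
        stable_tissue=classify_stability(geom.distension) == "stable",
        margin=margin,
        durable=margin > 0,
    )


# ---------------------------------------------------------------------------
# interobserver protocol


@dataclass(frozen=True)
class ObserverReadings:
    """Hernia-dimension readings, shape (observers, repeats), in cm."""

    readings: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.readings, dtype=float)
        object.__setattr__(self, "readings", arr)
        if arr.ndim != 2:
            raise ProtocolError("readings must be a 2-D observers x repeats matrix")
        if arr.shape[0] < 3:
            raise ProtocolError("at least three observers are required")
        if arr.shape[1] < 4:
            raise ProtocolError("at least four readings per observer are required")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ProtocolError("all readings must be finite and positive")


@dataclass(frozen=True)
class InterobserverResult:
    cv: float
    reliable: bool


def interobserver_check(readings: ObserverReadings) -> InterobserverResult:
    """Pooled coefficient of variation over all readings; reliable iff cv < 5%.

    The threshold is strict: a cv of exactly 5% is not reliable. The cv is
    permutation- and scale-invariant by construction (pooled sample SD over
    pooled mean).
    """
    flat = readings.readings.ravel()
    cv = float(np.std(flat, ddof=1) / np.mean(flat))
    return InterobserverResult(cv=cv, reliable=cv < INTEROBSERVER_CV_LIMIT)
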