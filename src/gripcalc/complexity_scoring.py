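"""Incisional-hernia complexity score.

One point per triggered risk category; the five comorbidity-related flags
(adverse metabolic consequences, elevated intra-abdominal pressure, bleeding
risk, reduced wound healing, abnormal gait) are collapsed into a single joint
point because their biomechanical effect — increased tissue laxity — is
shared. The eight point-bearing categories are:

===========================  =======================================
category label               trigger
===========================  =======================================
``large_defect``             defect width > 10 cm (strict)
``lateral_site``             lateral defect location
``recurrent``                recurrent hernia
``age_over_80``              age > 80 years (strict)
``bmi_over_30``              BMI > 30 kg/m2 (strict)
``comorbidity``              any of the five comorbidity flags
``stoma_or_bowel``           concomitant stoma or bowel repair
``intensified_surgery``      e.g. component separation
===========================  =======================================

Whether age and BMI belong to the collapsible comorbidity cluster is an open
modelling choice; here they are standalone categories (they are anatomically
distinct from the laxity-mediated comorbidities), so the maximum score is 8.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .registry_model import PatientProfile

DEFECT_WIDTH_THRESHOLD_CM = 10.0
AGE_THRESHOLD_YEARS = 80
BMI_THRESHOLD = 30.0

COMORBIDITY_FLAGS = (
    "metabolic_comorbidity",
    "elevated_iap",
    "bleeding_risk",
    "reduced_wound_healing",
    "abnormal_gait",
)

MAX_SCORE = 8


class ComplexityScore(BaseModel):
    """Result of scoring one profile: total points and their provenance."""

    model_config = ConfigDict(frozen=True)

    score: int = Field(ge=0, le=MAX_SCORE)
    triggered_categories: tuple[str, ...]
    comorbidity_collapsed: bool


def score_complexity(profile: PatientProfile) -> ComplexityScore:
    """Score a patient profile; deterministic, each point traceable.

    ``comorbidity_collapsed`` is True when two or more comorbidity flags were
    merged into the single joint point.
    """
    categories: list[str] = []
    if profile.defect_width > DEFECT_WIDTH_THRESHOLD_CM:
        categories.append("large_defect")
    if profile.lateral_site:
        categories.append("lateral_site")
    if profile.recurrent:
        categories.append("recurrent")
    if profile.age > AGE_THRESHOLD_YEARS:
        categories.append("age_over_80")
    if profile.bmi > BMI_THRESHOLD:
        categories.append("bmi_over_30")
    n_comorbid = sum(getattr(profile, flag) for flag in COMORBIDITY_FLAGS)
    if n_comorbid:
        categories.append("comorbidity")
    if profile.concomitant_stoma_or_bowel:
        categories.append("stoma_or_bowel")
    if profile.intensified_surgery:
        categories.append("intensified_surgery")
    return ComplexityScore(
        score=len(categories),
        triggered_categories=tuple(categories),
        comorbidity_collapsed=n_comorbid >= 2,
    )
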