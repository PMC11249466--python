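"""Domain types and I/O for hernia-registry records and GRIP coefficient tables.

The registry schema carries the demographic / comorbidity fields that feed the
complexity score, plus the seven extension items recorded for biomechanically
calculated reconstruction (mesh form, minimal overlap, number and kind of
fixation, pull-out/adapting sutures, peritoneal closure type and the
mesh-defect area ratio inputs).

Files are plain CSV: UTF-8, comma separator, decimal point, mandatory header.
Booleans are encoded 0/1; categorical labels are a lower_snake_case controlled
vocabulary (see ``SEXES``, ``POSITION_CLASSES``, ``FIXATION_TYPES``).
Unknown columns are preserved round-trip as opaque string extras.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterator, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError, RowValidationError, SchemaError

SEXES = ("female", "male")
POSITION_CLASSES = ("onlay", "retromuscular", "preperitoneal", "intraperitoneal_underlay")
FIXATION_TYPES = (
    "none",
    "absorbable_tack",
    "nonresorbable_suture",
    "pull_out_suture",
    "bone_anchor",
    "fibrin_glue",
)


class PatientProfile(BaseModel):
    """Demographics, hernia anatomy and risk-factor flags for one patient.

    Each boolean flag maps to exactly one risk category of the complexity
    score; the five ``*_comorbidity``-cluster flags (metabolic, elevated IAP,
    bleeding risk, reduced wound healing, abnormal gait) jointly contribute at
    most one complexity point.
    """

    model_config = ConfigDict(extra="forbid")

    patient_id: str
    age: int = Field(ge=0)
    sex: str
    bmi: float = Field(gt=0)
    preop_pain: int = Field(ge=0, le=10)
    defect_width: float = Field(gt=0)
    defect_length: float = Field(gt=0)
    lateral_site: bool = False
    recurrent: bool = False
    metabolic_comorbidity: bool = False
    elevated_iap: bool = False
    bleeding_risk: bool = False
    reduced_wound_healing: bool = False
    abnormal_gait: bool = False
    concomitant_stoma_or_bowel: bool = False
    intensified_surgery: bool = False

    @field_validator("sex")
    @classmethod
    def _sex_vocab(cls, v: str) -> str:
        if v not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {v!r}")
        return v


class MeshPlan(BaseModel):
    """The designed repair: mesh geometry, material classes, fixation, closure."""

    model_config = ConfigDict(extra="forbid")

    mesh_width: float = Field(gt=0)
    mesh_length: float = Field(gt=0)
    minimal_overlap: float = Field(ge=0)
    mesh_form: str = "flat_mesh"
    adhesiveness_class: str = "dis_class_a"
    position_class: str = "retromuscular"
    fixation_points: int = Field(ge=0)
    fixation_type: str = "none"
    peritoneal_closure: bool = False
    fascial_closure: bool = False

    @field_validator("position_class")
    @classmethod
    def _position_vocab(cls, v: str) -> str:
        if v not in POSITION_CLASSES:
            raise ValueError(f"position_class must be one of {POSITION_CLASSES}, got {v!r}")
        return v

    @field_validator("fixation_type")
    @classmethod
    def _fixation_vocab(cls, v: str) -> str:
        if v not in FIXATION_TYPES:
            raise ValueError(f"fixation_type must be one of {FIXATION_TYPES}, got {v!r}")
        return v


class OutcomeRecord(BaseModel):
    """Per-patient outcomes: stay, complications, re-operation and NAS pain.

    Pain is recorded on the 0-10 numeric analogue scale at discharge and at
    1 month / 6 months / 1 year / 3 years, split rest vs. exercise.
    A 3-year recurrence is representable but such records are reported
    separately from complexity-stratified summaries.
    """

    model_config = ConfigDict(extra="forbid")

    los_days: int = Field(ge=1)
    intraop_complication: bool = False
    postop_complication: bool = False
    reoperation_30d: bool = False
    pain_discharge: int = Field(ge=0, le=10)
    pain_1m_rest: int = Field(ge=0, le=10, default=0)
    pain_1m_exercise: int = Field(ge=0, le=10, default=0)
    pain_6m_rest: int = Field(ge=0, le=10, default=0)
    pain_6m_exercise: int = Field(ge=0, le=10, default=0)
    pain_1y_rest: int = Field(ge=0, le=10, default=0)
    pain_1y_exercise: int = Field(ge=0, le=10, default=0)
    pain_3y_rest: int = Field(ge=0, le=10, default=0)
    pain_3y_exercise: int = Field(ge=0, le=10, default=0)
    recurrence_3y: bool = False


PAIN_COLUMNS = (
    "pain_discharge",
    "pain_1m_rest",
    "pain_1m_exercise",
    "pain_6m_rest",
    "pain_6m_exercise",
    "pain_1y_rest",
    "pain_1y_exercise",
    "pain_3y_rest",
    "pain_3y_exercise",
)


class RegistryRecord(BaseModel):
    """One registry row: patient profile, mesh plan, outcome, optional extras.

    Iterating a record yields ``(profile, mesh, outcome)`` so rows unpack as
    triples. ``distension`` (cm, Valsalva) is optional because it is only
    recorded when a CT/ultrasound assessment was done; CRIP needs it.
    """

    model_config = ConfigDict(extra="forbid")

    profile: PatientProfile
    mesh: MeshPlan
    outcome: OutcomeRecord
    distension: Optional[float] = Field(default=None, ge=0)
    extras: dict[str, str] = Field(default_factory=dict)

    def __iter__(self) -> Iterator:  # type: ignore[override]
        return iter((self.profile, self.mesh, self.outcome))


class FixationBand(BaseModel):
    """One fixation-coefficient band: applies up to ``up_to`` points (inclusive);
    ``up_to`` None means unbounded."""

    model_config = ConfigDict(frozen=True)

    up_to: Optional[int] = None
    multiplier: float = Field(gt=0)


class CoefficientTable(BaseModel):
    """GRIP coefficients: multiplicative material/position/fixation terms and
    additive closure factors.

    All multipliers are strictly positive; a missing class lookup is a
    :class:`~gripcalc.errors.ConfigError`, never a silent default. The table
    is immutable once constructed. A fixation count of zero always maps to a
    neutral multiplier of 1 (no fixation contributes no grip).
    """

    model_config = ConfigDict(frozen=True)

    adhesiveness: dict[str, float]
    position: dict[str, float]
    fixation: dict[str, tuple[FixationBand, ...]]
    peritoneal_closure_factor: float = Field(ge=0)
    fascial_closure_factor: float = Field(ge=0)
    placeholder: bool = False

    @field_validator("adhesiveness", "position")
    @classmethod
    def _positive(cls, v: dict[str, float]) -> dict[str, float]:
        for key, mult in v.items():
            if not mult > 0:
                raise ValueError(f"multiplier for {key!r} must be > 0, got {mult}")
        return v

    def adhesiveness_for(self, klass: str) -> float:
        try:
            return self.adhesiveness[klass]
        except KeyError:
            raise ConfigError(f"no adhesiveness coefficient for class {klass!r}") from None

    def position_for(self, klass: str) -> float:
        try:
            return self.position[klass]
        except KeyError:
            raise ConfigError(f"no position coefficient for class {klass!r}") from None

    def fixation_for(self, fixation_type: str, points: int) -> float:
        if points < 0:
            raise ConfigError("fixation points must be >= 0")
        if points == 0:
            return 1.0
        try:
            bands = self.fixation[fixation_type]
        except KeyError:
            raise ConfigError(f"no fixation coefficients for type {fixation_type!r}") from None
        for band in bands:
            if band.up_to is None or points <= band.up_to:
                return band.multiplier
        raise ConfigError(
            f"no fixation band for type {fixation_type!r} covers {points} points"
        )

    @classmethod
    def identity(cls) -> "CoefficientTable":
        """All multipliers 1, closure factors 0: GRIP reduces to the MDAR.

        This is the shipped placeholder; clinically validated coefficients
        must be supplied via a config file.
        """
        return cls(
            adhesiveness={"dis_class_a": 1.0, "standard": 1.0},
            position={p: 1.0 for p in POSITION_CLASSES},
            fixation={t: (FixationBand(up_to=None, multiplier=1.0),) for t in FIXATION_TYPES},
            peritoneal_closure_factor=0.0,
            fascial_closure_factor=0.0,
            placeholder=True,
        )


# ---------------------------------------------------------------------------
# registry CSV I/O

_PROFILE_BOOLS = (
    "lateral_site",
    "recurrent",
    "metabolic_comorbidity",
    "elevated_iap",
    "bleeding_risk",
    "reduced_wound_healing",
    "abnormal_gait",
    "concomitant_stoma_or_bowel",
    "intensified_surgery",
)
_PROFILE_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "preop_pain",
    "defect_width",
    "defect_length",
) + _PROFILE_BOOLS

_MESH_BOOLS = ("peritoneal_closure", "fascial_closure")
_MESH_COLUMNS = (
    "mesh_width",
    "mesh_length",
    "minimal_overlap",
    "mesh_form",
    "adhesiveness_class",
    "position_class",
    "fixation_points",
    "fixation_type",
) + _MESH_BOOLS

_OUTCOME_BOOLS = (
    "intraop_complication",
    "postop_complication",
    "reoperation_30d",
    "recurrence_3y",
)
_OUTCOME_COLUMNS = ("los_days",) + PAIN_COLUMNS + _OUTCOME_BOOLS

MANDATORY_COLUMNS = _PROFILE_COLUMNS + _MESH_COLUMNS + _OUTCOME_COLUMNS
OPTIONAL_COLUMNS = ("distension",)

_ALL_BOOLS = set(_PROFILE_BOOLS) | set(_MESH_BOOLS) | set(_OUTCOME_BOOLS)


def _parse_bool(raw: str, column: str) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise ValueError(f"{column} must be 0 or 1, got {raw!r}")


def _validation_message(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def read_registry(path: str | Path) -> list[RegistryRecord]:
    """Read and validate a registry CSV.

    Raises :class:`SchemaError` naming the first missing mandatory column and
    :class:`RowValidationError` (with the 0-based data-row index) on the first
    invariant violation. Unknown columns survive as ``record.extras``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing mandatory column {col!r}")
        known = set(MANDATORY_COLUMNS) | set(OPTIONAL_COLUMNS)
        extra_cols = [c for c in header if c not in known]

        records: list[RegistryRecord] = []
        for idx, row in enumerate(reader):
            try:
                records.append(_row_to_record(row, extra_cols))
            except ValidationError as exc:
                raise RowValidationError(idx, _validation_message(exc)) from exc
            except ValueError as exc:
                raise RowValidationError(idx, str(exc)) from exc
    return records


def _row_to_record(row: dict[str, str], extra_cols: list[str]) -> RegistryRecord:
    def field(col: str) -> str:
        raw = row.get(col)
        if raw is None:
            raise ValueError(f"missing value for column {col!r}")
        return raw.strip()

    def build(columns: tuple[str, ...]) -> dict:
        out: dict = {}
        for col in columns:
            raw = field(col)
            out[col] = _parse_bool(raw, col) if col in _ALL_BOOLS else raw
        return out

    profile = PatientProfile(**build(_PROFILE_COLUMNS))
    mesh = MeshPlan(**build(_MESH_COLUMNS))
    outcome = OutcomeRecord(**build(_OUTCOME_COLUMNS))
    distension_raw = (row.get("distension") or "").strip()
    distension = float(distension_raw) if distension_raw else None
    extras = {c: (row.get(c) or "") for c in extra_cols}
    return RegistryRecord(
        profile=profile, mesh=mesh, outcome=outcome, distension=distension, extras=extras
    )


def _record_to_row(rec: RegistryRecord, extra_cols: list[str]) -> dict[str, str]:
    row: dict[str, str] = {}
    for model, columns in (
        (rec.profile, _PROFILE_COLUMNS),
        (rec.mesh, _MESH_COLUMNS),
        (rec.outcome, _OUTCOME_COLUMNS),
    ):
        for col in columns:
            value = getattr(model, col)
            if col in _ALL_BOOLS:
                row[col] = "1" if value else "0"
            elif isinstance(value, float):
                row[col] = format(value, "g")
            else:
                row[col] = str(value)
    row["distension"] = "" if rec.distension is None else format(rec.distension, "g")
    for col in extra_cols:
        row[col] = rec.extras.get(col, "")
    return row


def write_registry(records: list[RegistryRecord], path: str | Path) -> None:
    """Write records to CSV such that :func:`read_registry` round-trips them."""
    path = Path(path)
    extra_cols = sorted({c for rec in records for c in rec.extras})
    header = list(MANDATORY_COLUMNS) + ["distension"] + extra_cols
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=header)
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec, extra_cols))


# ---------------------------------------------------------------------------
# coefficient config I/O

_SECTIONS = (
    "adhesiveness",
    "position",
    "fixation",
    "peritoneal_closure_factor",
    "fascial_closure_factor",
)


def read_coefficients(path: str | Path) -> CoefficientTable:
    """Load a coefficient table from a JSON or YAML config file.

    The config must contain the five sections ``adhesiveness``, ``position``,
    ``fixation``, ``peritoneal_closure_factor`` and ``fascial_closure_factor``.
    Any non-positive multiplier or missing section is a :class:`ConfigError`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("coefficient config must be a mapping")
    for section in _SECTIONS:
        if section not in data:
            raise ConfigError(f"missing section {section!r}")
    try:
        return CoefficientTable(
            adhesiveness=data["adhesiveness"],
            position=data["position"],
            fixation={
                t: tuple(FixationBand(**band) for band in bands)
                for t, bands in data["fixation"].items()
            },
            peritoneal_closure_factor=data["peritoneal_closure_factor"],
            fascial_closure_factor=data["fascial_closure_factor"],
            placeholder=bool(data.get("placeholder", False)),
        )
    except (ValidationError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def write_coefficients(table: CoefficientTable, path: str | Path) -> None:
    """Serialize a coefficient table to JSON or YAML (by file extension)."""
    path = Path(path)
    data = {
        "adhesiveness": dict(table.adhesiveness),
        "position": dict(table.position),
        "fixation": {
            t: [{"up_to": b.up_to, "multiplier": b.multiplier} for b in bands]
            for t, bands in table.fixation.items()
        },
        "peritoneal_closure_factor": table.peritoneal_closure_factor,
        "fascial_closure_factor": table.fascial_closure_factor,
        "placeholder": table.placeholder,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
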