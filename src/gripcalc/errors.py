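"""Exception hierarchy shared across the package."""


class GripError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GripError):
    """A registry file is missing a mandatory column."""


class RowValidationError(GripError):
    """A registry row violates a type invariant.

    Carries the 0-based data-row index (header excluded) in ``row_index``.
    """

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class ConfigError(GripError):
    """A coefficient config is malformed or incomplete."""


class DomainError(GripError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ProtocolError(GripError):
    """The interobserver measurement protocol is not satisfied."""


class DataError(GripError):
    """A displacement field or grid contains invalid (non-finite) data."""


class InfeasibleRepairError(GripError):
    """No plan within the planner constraints achieves GRIP > CRIP.

    ``best_plan`` / ``best_assessment`` describe the closest candidate and
    ``margin`` its (negative) GRIP - CRIP margin.
    """

    def __init__(self, best_plan, best_assessment, margin: float):
        self.best_plan = best_plan
        self.best_assessment = best_assessment
        self.margin = margin
        super().__init__(
            f"no feasible repair within constraints; best margin {margin:.3f}"
        )


class UndersizedMeshWarning(UserWarning):
    """A mesh plan is smaller than the defect in at least one dimension."""
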