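"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`NucsoxError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class NucsoxError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(NucsoxError, ValueError):
    """An argument violates a documented precondition."""


class PDBParseError(NucsoxError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class RosterError(NucsoxError):
    """Trajectory frames disagree on their atom roster."""


class SelectionError(NucsoxError):
    """A selection names an atom or residue that is absent."""


class DuplexInferenceError(NucsoxError):
    """Strand pairing failed; carries a pairing report."""

    def __init__(self, message: str, report: dict | None = None):
        self.report = report or {}
        super().__init__(message)


class ConditioningError(NucsoxError):
    """Point set too degenerate for a unique superposition."""


class GeometryError(NucsoxError):
    """A geometric profile cannot be computed from the given structure."""


class StatisticsError(NucsoxError):
    """Too few observations for the requested statistic."""


class PlacementError(NucsoxError):
    """A designed probe atom cannot be placed without a steric clash."""


class NormalizationError(NucsoxError):
    """Band-intensity normalization is ill-defined (zero standard)."""


class FitError(NucsoxError):
    """All fit starts failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        self.diagnostics = diagnostics or []
        super().__init__(message)


class ExtractionError(NucsoxError):
    """No half-change concentration exists in the assayed range."""


class ConfigError(NucsoxError):
    """Pipeline configuration is invalid; carries all violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class StageError(NucsoxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
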