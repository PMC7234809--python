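"""Exception hierarchy shared across the package."""


class TojReplayError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TojReplayError):
    """A trial table is missing required columns."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"trial table missing required column(s): {', '.join(self.missing)}")


class RowParseError(TojReplayError):
    """One or more rows could not be parsed into the expected types."""

    def __init__(self, column, rows):
        self.column = column
        self.rows = tuple(rows)
        super().__init__(
            f"non-numeric values in column '{column}' at row(s) {list(self.rows)}"
        )


class InvariantViolation(TojReplayError):
    """Trial-level invariants violated; carries per-row messages."""

    def __init__(self, violations):
        # violations: list of (row_index, message)
        self.violations = list(violations)
        head = "; ".join(f"row {r}: {m}" for r, m in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"trial invariant violation(s): {head}{more}")


class DegenerateTrialError(TojReplayError):
    """A trial is degenerate for the requested computation (e.g. equal probes)."""


class DesignInfeasibleError(TojReplayError):
    """Probe placement geometrically impossible for a designed trial."""


class InsufficientDataError(TojReplayError):
    """Too few observations for the requested fit."""


class DegenerateDataError(TojReplayError):
    """Data carry no variance (or otherwise defeat the estimator)."""


class ConvergenceError(TojReplayError):
    """The optimizer did not converge."""

    def __init__(self, variant, n_iter):
        self.variant = variant
        self.n_iter = n_iter
        super().__init__(f"optimizer failed to converge for variant '{variant}' after {n_iter} iterations")


class EmptySegmentError(TojReplayError):
    """A chosen-frame-location segment received no trials."""

    def __init__(self, segment, n_segments):
        self.segment = segment
        self.n_segments = n_segments
        super().__init__(
            f"segment {segment + 1} of {n_segments} is empty; consider fewer segments"
        )


class CapabilityError(TojReplayError):
    """An optional backend/dependency is unavailable."""


class NoFeaturesError(TojReplayError):
    """No keypoints detected in at least one image of a pair."""


class ConfigError(TojReplayError):
    """Pipeline configuration is invalid or incomplete."""
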