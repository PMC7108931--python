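"""Exception hierarchy.

Three error families map onto distinct CLI exit codes: configuration
errors (bad thresholds, unknown labels), input errors (malformed or
inconsistent data), and statistical degeneracy (tests that cannot be
computed on the given table).
"""


class PtasigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PtasigError):
    """A parameter or option is outside its valid range or refers to an
    unknown label/tissue/subset."""


class InputError(PtasigError):
    """Input data violate a precondition (malformed file, duplicate ids,
    non-finite values, mismatched gene universes, ...)."""


class DegenerateTableError(InputError):
    """A contingency table has a zero margin, so the exact test is
    undefined."""


class PipelineStageError(PtasigError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


class UnstableEstimateWarning(UserWarning):
    """A permutation-based estimate rests on too few (or no) null values
    of the required sign and should not be trusted."""
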