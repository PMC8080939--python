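"""Exception hierarchy shared across modules."""


class MethylProfilerError(Exception):
    """Base class for all package errors."""


class FormatError(MethylProfilerError):
    """File could not be parsed as the expected format."""


class SchemaError(MethylProfilerError):
    """File parsed but required columns/structure are missing."""


class ValidationError(MethylProfilerError):
    """Contents violate a documented constraint."""


class AmbiguousOrientationError(ValidationError):
    """Neither or both axes of a matrix look like CpG identifiers."""


class ScaleDetectionError(ValidationError):
    """Value scale could not be decided (e.g. all entries missing)."""


class MissingCpGError(MethylProfilerError):
    """CpGs required by a predictor are absent from matrix and panel."""

    def __init__(self, cpg_ids):
        self.cpg_ids = list(cpg_ids)
        super().__init__(
            "required CpG sites absent from both the matrix and the "
            f"reference panel: {', '.join(self.cpg_ids)}"
        )


class ConfigurationError(MethylProfilerError):
    """Inconsistent run configuration (e.g. duplicate trait names)."""


class ProfilingError(MethylProfilerError):
    """A profiling panel cannot be produced for the current subset."""
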