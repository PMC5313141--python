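"""Exception hierarchy shared across the pipeline."""


class StrokeBbbError(Exception):
    """Base class for all package errors."""


class ParameterError(StrokeBbbError, ValueError):
    """A physical or acquisition parameter is out of its valid range."""


class GeometryError(StrokeBbbError, ValueError):
    """Volumes/masks disagree in shape, orientation or required layout."""


class FitError(StrokeBbbError, RuntimeError):
    """A voxel/ROI model fit is undefined (too few points, degenerate design)."""


class CohortSpecError(ParameterError):
    """A cohort-generation specification is internally inconsistent."""


class SchemaError(StrokeBbbError, ValueError):
    """A cohort table is missing required columns after mapping."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "cohort table is missing required columns: " + ", ".join(self.missing)
        )


class StageError(StrokeBbbError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
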