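"""Exception hierarchy shared across the pipeline stages."""


class SignalNicheError(Exception):
    """Base class for all package-specific errors."""


class InvalidProfileError(SignalNicheError, ValueError):
    """A species profile violates its invariants."""


class DataIntegrityError(SignalNicheError, ValueError):
    """Input tables are internally inconsistent (e.g. one individual under
    two species codes, or a required field is missing)."""


class DegenerateInputError(SignalNicheError, ValueError):
    """Numerically degenerate input (constant trait column, zero-area hull)."""


class DegenerateNicheError(DegenerateInputError):
    """A species has too few or exactly collinear score points for a 2-D hull."""

    def __init__(self, species: str, reason: str = "collinear or too few points"):
        self.species = species
        super().__init__(f"degenerate niche for species {species!r}: {reason}")


class ConfigError(SignalNicheError, ValueError):
    """Invalid pipeline or simulation configuration."""


class PipelineStageError(SignalNicheError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
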