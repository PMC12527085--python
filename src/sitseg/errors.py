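"""Exception hierarchy shared across the package."""


class SitsegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SitsegError, ValueError):
    """A file or table does not conform to the expected dialect."""


class IntegrityError(SitsegError, ValueError):
    """Data is syntactically valid but violates a signal invariant
    (e.g. non-uniform timestamps)."""


class ParameterError(SitsegError, ValueError):
    """An argument is outside its admissible range."""


class LengthError(SitsegError, ValueError):
    """A signal is too short for the requested operation."""


class DegenerateFeatureError(SitsegError, ValueError):
    """A feature has no spread between its normalization percentiles."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(
            f"feature {feature!r} has P95 == P5; cannot normalize a constant feature"
        )


class TrainingError(SitsegError, ValueError):
    """The training set cannot support fitting (e.g. a single class)."""


class SchemaError(SitsegError, ValueError):
    """Feature columns do not match what a trained model expects."""
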