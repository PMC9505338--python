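"""Exception hierarchy. All package errors derive from ThermostabError."""


class ThermostabError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(ThermostabError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class SequenceValidationError(ThermostabError):
    """A sequence failed validation against the 20-letter standard alphabet."""

    def __init__(self, message: str, offending: str | None = None):
        super().__init__(message)
        self.offending = offending


class DataError(ThermostabError):
    """Invalid tabular input, target values, or split parameters."""


class FeatureError(ThermostabError):
    """A record violates a descriptor-family precondition, or a feature
    matrix does not carry the columns a model requires."""


class ModelIOError(ThermostabError):
    """A model artifact could not be read, or is version-incompatible."""
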