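"""Exception hierarchy for the leaf segmentation pipeline."""


class LeafSegError(Exception):
    """Base class for all pipeline errors."""


class InputError(LeafSegError):
    """Invalid input data (dimension mismatch, wrong bit depth, ...)."""


class EmptyInputError(InputError):
    """An operation received an image with no usable (valid-depth) pixels."""


class ConfigError(LeafSegError):
    """Malformed or out-of-range configuration values."""

    def __init__(self, message, keys=()):
        super().__init__(message)
        self.keys = tuple(keys)


class NumericalError(LeafSegError):
    """A numerical scheme became unstable (non-finite values)."""


class GenerationError(LeafSegError):
    """The synthetic scene generator could not satisfy placement constraints."""
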