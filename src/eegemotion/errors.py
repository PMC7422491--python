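"""Exception hierarchy shared across the pipeline."""


class EegEmotionError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(EegEmotionError):
    """Invalid design, signature, or run-configuration value."""


class InputError(EegEmotionError):
    """Data handed to an operation violates its contract."""


class DegenerateSignalError(InputError):
    """Signal has zero variance (or is otherwise featureless)."""


class FormatError(InputError):
    """A file on disk is not in the expected on-disk format."""
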