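"""Exception types shared across the package."""


class EmgDryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmgDryError, ValueError):
    """A protocol, activation, electrode or training configuration is invalid."""


class ParseError(EmgDryError, ValueError):
    """A session or segment file could not be parsed."""


class ValidationError(EmgDryError, ValueError):
    """An in-memory object violates a structural invariant (e.g. a non-binary
    movement indicator)."""


class UndefinedSNRError(EmgDryError, ValueError):
    """SNR is undefined because contraction or rest segments are missing."""


class FeatureMismatchError(EmgDryError, ValueError):
    """A model and a dataset disagree on the feature columns."""


class SplitError(EmgDryError, ValueError):
    """A train/test split cannot be constructed from the available trials."""
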