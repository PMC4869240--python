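"""Exception types shared across the package."""


class AwareliftError(Exception):
    """Base class for package errors."""


class PanelFormatError(AwareliftError, ValueError):
    """A panel file does not have the expected layout (missing columns, bad header)."""


class StreamDataError(AwareliftError, ValueError):
    """Stream contents violate a data contract (gaps, duplicates, negative values,
    zero denominators)."""


class DegenerateInputError(AwareliftError, ValueError):
    """An operation is undefined for this input (e.g. rescaling an all-zero series)."""


class EstimationError(AwareliftError, RuntimeError):
    """Model fitting or effect estimation failed."""
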