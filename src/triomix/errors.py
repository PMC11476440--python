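"""Exception types shared across the package."""


class TriomixError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TriomixError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(TriomixError, ValueError):
    """Parsed data violate an invariant (negative counts, duplicate ids, ...)."""


class CapacityError(TriomixError, ValueError):
    """A simulation request cannot be satisfied (e.g. genes do not fit on the genome)."""
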