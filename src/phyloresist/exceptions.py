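"""Exception hierarchy shared across the package."""


class PhyloresistError(Exception):
    """Base class for all package errors."""


class ValidationError(PhyloresistError, ValueError):
    """Input violates a documented invariant (negative count, bad enum, ...)."""


class FormatError(PhyloresistError, ValueError):
    """A file could not be parsed as the expected format."""


class TreeLookupError(PhyloresistError, KeyError):
    """A species name is not a tip of the phylogeny."""

    def __init__(self, missing):
        self.missing = sorted(missing) if not isinstance(missing, str) else [missing]
        super().__init__("species not found in tree: " + ", ".join(self.missing))


class DegenerateInputError(PhyloresistError, ValueError):
    """A statistic is undefined for this input (e.g. all-identical gradient)."""
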