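"""Exception types shared across the toolkit."""


class CaptorKitError(Exception):
    """Base class for all captorkit errors."""


class InvalidParameterError(CaptorKitError, ValueError):
    """A parameter is outside its documented valid range."""


class InvalidSequenceError(CaptorKitError, ValueError):
    """A sequence contains characters outside the DNA alphabet."""


class InvalidInputError(CaptorKitError, ValueError):
    """An input collection is empty or otherwise unusable."""


class DesignInfeasibleError(CaptorKitError, RuntimeError):
    """Panel design constraints cannot be satisfied.

    Carries a human-readable description of the violated constraint.
    """


class FormatError(CaptorKitError, ValueError):
    """A file does not conform to its expected format.

    ``path`` and ``line`` identify the offending record when known.
    """

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class OutOfBoundsError(CaptorKitError, ValueError):
    """A genomic interval falls outside its contig."""


class InsufficientDataError(CaptorKitError, ValueError):
    """Not enough observations to perform the requested fit."""


class ConsistencyError(CaptorKitError, ValueError):
    """Internal cross-references between artefacts disagree."""
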