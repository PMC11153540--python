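"""Exception hierarchy shared across the pipeline."""


class MorphorateError(Exception):
    """Base class for all package errors."""


class ParseError(MorphorateError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(MorphorateError):
    """Parsed data violate a structural invariant."""


class DegenerateInputError(MorphorateError):
    """Input is syntactically valid but geometrically degenerate."""
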