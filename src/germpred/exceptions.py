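"""Exception hierarchy for germpred."""


class GermpredError(Exception):
    """Base class for all germpred errors."""


class ValidationError(GermpredError, ValueError):
    """Input data violates a container invariant."""


class ParseError(GermpredError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class EmptyPanelError(GermpredError, ValueError):
    """Marker filtering removed every marker."""


class ConvergenceError(GermpredError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostic context."""
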