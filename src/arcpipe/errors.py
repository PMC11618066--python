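"""Exception hierarchy shared by all pipeline stages."""


class ArcpipeError(Exception):
    """Base class for all arcpipe errors."""


class ConfigurationError(ArcpipeError, ValueError):
    """A generator or pipeline configuration violates its invariants."""


class DegenerateInputError(ArcpipeError, ValueError):
    """Input is structurally valid but degenerate (e.g. constant reference
    channel, zero-variance paired differences)."""


class CorrectionInfeasibleError(ArcpipeError, ValueError):
    """The isosbestic correction cannot be applied, e.g. the fitted
    reference trace is not strictly positive so the ratiometric %dF/F is
    undefined."""


class EmptyResultError(ArcpipeError, ValueError):
    """An operation removed every cell/trial, leaving nothing downstream."""


class AlignmentError(ArcpipeError, ValueError):
    """No usable events remain after coverage exclusions."""
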