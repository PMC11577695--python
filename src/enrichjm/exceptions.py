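"""Exception types raised across the package."""


class EnrichjmError(Exception):
    """Base class for package errors."""


class InsufficientEvents(EnrichjmError):
    """Fewer events than requested ever occur in the trigger population."""


class InsufficientMeasurements(EnrichjmError):
    """A trajectory fit was requested with fewer than two usable measurements."""


class NoResidualDf(EnrichjmError):
    """No subject contributes residual degrees of freedom to the pooled variance."""


class RootNotFound(EnrichjmError):
    """The estimating-equation solver failed to converge from every start."""


class InfeasibleSpend(EnrichjmError):
    """A spent error exceeds the probability mass attainable by any boundary."""
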