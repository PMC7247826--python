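"""Exception hierarchy for ucnsim."""


class UCNError(Exception):
    """Base class for all ucnsim errors."""


class ConfigurationError(UCNError):
    """A circuit, device or scenario configuration is inconsistent or incomplete."""


class InputError(UCNError, ValueError):
    """An operation received an out-of-domain input (non-finite, wrong sign, ...)."""


class IntegrationError(UCNError):
    """The hybrid integrator failed (chattering, non-finite state, solver failure)."""


class AnalysisError(UCNError):
    """A spike-train analysis precondition was violated (too few spikes, empty trace)."""


class TraceIOError(UCNError):
    """A trace file could not be parsed (missing column, empty file)."""
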