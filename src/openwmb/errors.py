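"""Exception hierarchy for the battery toolkit."""


class OpenWMBError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(OpenWMBError, ValueError):
    """A parameter or task configuration violates a structural constraint."""


class PoolValidationError(OpenWMBError, ValueError):
    """A sentence pool row violates the sentence constraints.

    Carries ``line`` (1-based line number in the source file, when known)
    and ``offending`` (list of offending rows) attributes.
    """

    def __init__(self, message, line=None, offending=None):
        super().__init__(message)
        self.line = line
        self.offending = offending or []


class SchemaError(OpenWMBError, ValueError):
    """A trial log or score table does not match the expected schema."""


class AbortedSessionError(OpenWMBError, RuntimeError):
    """A responder callback failed mid-session.

    The partial trial log collected up to the failure is available on the
    ``records`` attribute.
    """

    def __init__(self, message, records=None):
        super().__init__(message)
        self.records = records or []


class ModelFitError(OpenWMBError, RuntimeError):
    """A factor/SEM model could not be estimated (non-convergence,
    under-identification, or a singular matrix)."""
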