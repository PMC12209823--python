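"""Exception types shared across the package."""


class WsimilError(Exception):
    """Base class for package errors."""


class ConfigurationError(WsimilError):
    """A configuration is internally inconsistent or infeasible."""


class ManifestError(WsimilError):
    """A cohort manifest violates a referential or label invariant."""


class EmbeddingIOError(WsimilError):
    """An embedding container or its coordinate sidecar is malformed."""
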