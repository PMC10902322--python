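"""Exception hierarchy shared across the package."""


class OccAuditError(Exception):
    """Base class for all package errors."""


class ConfigError(OccAuditError):
    """Invalid configuration: bad field map, malformed rule table, bad CLI flags."""


class DataValidationError(OccAuditError):
    """Input data violates a contract that cannot be repaired by flagging."""
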