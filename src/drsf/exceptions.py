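"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the field."""


class ContractViolationError(ValueError):
    """An input violates an operation's contract (e.g. unknown feature)."""


class UndefinedMetricError(ValueError):
    """A metric has no defined value on the given data (e.g. no comparable pairs)."""
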