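"""Exception hierarchy.

``ConfigError`` covers invalid parameters and malformed configuration,
``DataError`` covers input tables that violate the pipeline's contracts.
The command-line layer maps them to exit codes 1 and 2 respectively.
"""


class SnoclassError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SnoclassError):
    """Invalid parameter value or malformed configuration."""


class DataError(SnoclassError):
    """Input data violates a contract (bad table, impossible request)."""
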