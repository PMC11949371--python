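"""Exception hierarchy.

ConfigError maps to CLI exit code 2, IntegrityError to exit code 3.
"""


class RespondError(Exception):
    """Base class for all package errors."""


class ConfigError(RespondError):
    """Invalid, inconsistent, or missing configuration/input."""


class IntegrityError(RespondError):
    """Numerical integrity violated during simulation (e.g. negative occupancy)."""
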