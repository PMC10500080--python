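"""Exception hierarchy.

``DataError`` covers anything wrong with the *inputs* (malformed files,
broken referential integrity, contradictory configuration); everything
else is an ordinary programming error.
"""


class DataError(Exception):
    """Base class for input-data problems."""


class FormatError(DataError):
    """A file does not parse in its declared dialect."""


class IntegrityError(DataError):
    """Parsed data violates a structural invariant (cycles, orphans, ...)."""


class ConfigError(DataError):
    """Invalid or contradictory user configuration."""
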