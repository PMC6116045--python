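"""Exception hierarchy for data and format errors."""


class DbpstackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DbpstackError):
    """A file does not conform to its expected textual format."""


class ProfileError(DbpstackError):
    """A profile's contents violate a contract (shape, range, length)."""


class SchemaError(DbpstackError):
    """Inconsistent feature-block structure across records or models."""
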