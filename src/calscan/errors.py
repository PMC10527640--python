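"""Exception hierarchy shared across the package."""


class CalscanError(Exception):
    """Base class for all calscan errors."""


class InputError(CalscanError):
    """A file is missing, unreadable, or not of the expected kind."""


class SchemaError(CalscanError):
    """Sidecar metadata lacks a required field or has the wrong type."""


class ValidationError(CalscanError):
    """Values are present but physically or structurally invalid."""


class PairingError(CalscanError):
    """A paired-protocol computation was requested on an incomplete set."""
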