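"""Exception hierarchy shared across the package."""


class HemedistError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(HemedistError):
    """Raised when a PDB file cannot be parsed under the package's contracts."""


class StructureError(HemedistError):
    """Raised when an atom/residue selection cannot be resolved uniquely."""


class MutationError(HemedistError):
    """Raised when a missense mutation does not match the target sequence."""


class MSAError(HemedistError):
    """Raised for malformed alignments or invalid alignment coordinates."""


class ConfigError(HemedistError):
    """Raised for invalid or unknown run-configuration values."""
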