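"""Exception hierarchy shared across the package."""


class KrabstratError(Exception):
    """Base class for all package errors."""


class ValidationError(KrabstratError):
    """Invalid arguments or violated invariants (CLI exit code 2)."""


class AlphabetError(ValidationError):
    """A character outside the accepted amino-acid alphabet."""


class DataError(KrabstratError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class ParseError(DataError):
    """A file could not be parsed; message names the offending line."""


class CalibrationError(KrabstratError):
    """E-value calibration failed or was never performed."""


class UnderdeterminedConstructError(KrabstratError):
    """A mutant construct whose residue composition is not fully specified."""
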