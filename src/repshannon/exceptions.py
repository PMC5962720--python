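"""Exception hierarchy for repshannon."""


class RepShannonError(Exception):
    """Base class for all repshannon errors."""


class FormatError(RepShannonError, ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(RepShannonError, ValueError):
    """Input data violate a domain invariant (alphabet, counts, translation)."""


class CalibrationError(RepShannonError, RuntimeError):
    """The rank-abundance model could not be calibrated to its richness anchor."""
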