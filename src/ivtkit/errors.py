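"""Exception hierarchy for ivtkit."""


class IvtKitError(Exception):
    """Base class for all ivtkit errors."""


class ConfigurationError(IvtKitError):
    """Invalid parameter or configuration value."""


class InputError(IvtKitError):
    """Malformed or inconsistent input data."""


class TruthSetError(IvtKitError):
    """Simulation truth set disagrees with the reference sequence."""


class ReferenceMismatchError(IvtKitError):
    """Two datasets disagree about the reference base at a coordinate."""


class InsufficientDataError(IvtKitError):
    """Too few observations to compute the requested statistic."""
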