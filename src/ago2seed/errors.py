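"""Exception hierarchy shared across the pipeline stages."""


class Ago2SeedError(Exception):
    """Base class for all package errors."""


class ProbeTableFormatError(Ago2SeedError):
    """Probe table file does not match the documented dialect."""


class ProbeValidationError(Ago2SeedError):
    """Probe table parsed but carries invalid values (e.g. negative intensity)."""


class NormalizationError(Ago2SeedError):
    """Normalization preconditions violated (all-zero sample, too few fit probes)."""


class SimulationError(Ago2SeedError):
    """Simulation design cannot be realized."""


class FixtureError(Ago2SeedError):
    """Packaged reference table is missing or corrupted."""


class SequenceError(Ago2SeedError):
    """Sequence contains non-canonical characters or violates length bounds."""
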