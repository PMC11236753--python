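"""Exception hierarchy for the forearm stimulation twin."""


class FestwinError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(FestwinError):
    """Invalid phantom geometry or electrode placement."""


class SolverError(FestwinError):
    """Volume-conductor solve failed (singular system or non-convergence)."""


class ModelError(FestwinError):
    """Nerve-model input or integration problem."""


class ConfigError(FestwinError):
    """Invalid or incomplete run configuration."""
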