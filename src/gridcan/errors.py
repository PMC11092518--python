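"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid model, preset, or run configuration."""


class FormatError(ValueError):
    """Malformed input file (trajectory CSV, run archive, ...)."""


class SimulationError(RuntimeError):
    """Numerical failure during a simulation run (non-finite state)."""


class AnalysisError(ValueError):
    """An analysis is undefined for the given input (e.g. no occupancy)."""
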