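"""Exception types. ``DataError`` maps to CLI exit code 3."""


class ExofootError(Exception):
    """Base class for package errors."""


class DataError(ExofootError, ValueError):
    """Malformed or out-of-range input data."""


class ConfigError(ExofootError, ValueError):
    """Invalid or infeasible run configuration."""


class SimulationError(ExofootError, RuntimeError):
    """A simulation draw could not be completed (e.g. retry budget exhausted)."""
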