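"""Exception hierarchy shared across the toolkit."""


class MfepError(Exception):
    """Base class for all toolkit errors."""


class InputError(MfepError, ValueError):
    """Invalid user input (mismatched shapes, bad names, out-of-range indices)."""


class DegeneracyError(MfepError, ValueError):
    """Geometric degeneracy: collinear/coincident points, isotropic clouds."""


class ConfigError(MfepError, ValueError):
    """Invalid configuration values (unknown preset, non-divisible durations)."""


class IntegrationError(MfepError, RuntimeError):
    """Trajectory left the guarded domain during propagation."""


class ConvergenceError(MfepError, RuntimeError):
    """An iterative solver exceeded its iteration budget."""


class EstimationError(MfepError, RuntimeError):
    """A statistical estimator could not produce a result (e.g. unbracketed root)."""


class ParseError(MfepError, ValueError):
    """Malformed input file."""


class NumericalError(MfepError, RuntimeError):
    """A numerical routine failed its internal accuracy self-check."""
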