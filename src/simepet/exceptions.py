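"""Exception hierarchy for simepet.

All library errors derive from :class:`SimepetError` so callers (and the CLI)
can distinguish user-input problems from fitting problems.
"""


class SimepetError(Exception):
    """Base class for all simepet errors."""


class InvalidParameterError(SimepetError, ValueError):
    """A kinetic or model parameter is outside its admissible domain."""


class CoverageError(SimepetError, ValueError):
    """An input-function time grid does not span the requested frame schedule."""


class InsufficientDataError(SimepetError, ValueError):
    """Too few usable samples to fit a blood model."""


class InvalidSampleError(SimepetError, ValueError):
    """A blood sample violates its invariants (e.g. zero plasma activity)."""


class ModelDomainError(SimepetError, ValueError):
    """A fitted model is evaluated where it is not defined (e.g. BPR <= 0)."""


class ScalingError(SimepetError, ValueError):
    """IDIF scaling is impossible (no overlapping times or degenerate curve)."""


class DegenerateFitError(SimepetError, ValueError):
    """The data carry no information for the requested fit (e.g. all-zero TAC)."""


class DegenerateRegressionError(SimepetError, ValueError):
    """Regression impossible: zero variance in the predictor."""


class UnboundedVTError(SimepetError, ValueError):
    """k4 = 0 with k3 > 0: the total distribution volume diverges."""


class EmptyResultError(SimepetError, ValueError):
    """An operation produced no frames/rows (e.g. truncation removed everything)."""


class ParseError(SimepetError, ValueError):
    """A CSV or config file violates the documented dialect."""


class AnalysisError(SimepetError, RuntimeError):
    """A composite analysis failed systematically (e.g. most Monte Carlo reps)."""
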