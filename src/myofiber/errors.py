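"""Exception hierarchy for myofiber."""


class MyofiberError(Exception):
    """Base class for all myofiber errors."""


class ModelError(MyofiberError):
    """Kinetic model is degenerate (e.g. all rates zero) or produced a
    non-finite state."""


class FitError(MyofiberError):
    """Nonlinear least squares failed to converge."""


class DegenerateDataError(FitError):
    """Input data carry no signal to fit (flat trace, constant response)."""


class IdentifiabilityError(FitError):
    """Data do not constrain the model parameters (too few distinct levels,
    no dynamic range)."""


class WindowError(MyofiberError):
    """No valid fit window could be located in a force trace."""


class TraceFormatError(MyofiberError):
    """A force-trace file does not conform to the two-column text format."""


class SchemaError(MyofiberError):
    """A measurement table is missing required columns or is empty."""
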