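"""Exception hierarchy for altsense.

All errors raised by the library derive from :class:`AltSenseError` so that
callers (and the CLI) can catch one base class.  Schema problems in CSV files
raise :class:`SchemaError` with the offending column / key named; invalid
numeric inputs raise :class:`ValidationError`; a min-max rescale of a flat
trace raises :class:`DegenerateTraceError`.
"""


class AltSenseError(Exception):
    """Base class for all altsense errors."""


class ValidationError(AltSenseError, ValueError):
    """An input violated a documented precondition."""


class SchemaError(AltSenseError, ValueError):
    """A CSV file violated the expected schema; message names the problem."""


class SimulationError(AltSenseError, RuntimeError):
    """The ODE integrator failed; never silently returns NaN."""


class DegenerateTraceError(AltSenseError, ValueError):
    """A trace has (near-)zero range and cannot be rescaled to percent full scale."""
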