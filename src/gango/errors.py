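"""Exception types distinguishing input problems from numerical failures."""


class GangoError(Exception):
    """Base class for pipeline errors."""


class InputError(GangoError, ValueError):
    """Malformed or out-of-contract input (bad shapes, ranges, formats)."""


class DegenerateDataError(GangoError, ValueError):
    """Data degenerate for the requested operation (constant series, zero baseline)."""


class NumericalError(GangoError, ArithmeticError):
    """Numerical failure (singular regression, non-finite values)."""
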