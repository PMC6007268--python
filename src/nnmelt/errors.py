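"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit 2,
numerical/transition failures exit 3.
"""


class NNMeltError(Exception):
    """Base class for all package errors."""


class ValidationError(NNMeltError):
    """Input data violates a documented contract."""


class ParseError(ValidationError):
    """A text input could not be parsed; message names the offending line."""


class DegenerateBaselineError(NNMeltError):
    """Upper baseline does not lie above the lower baseline where required."""


class NoTransitionError(NNMeltError):
    """A melting curve never crosses the half-paired point."""


class NumericalError(NNMeltError):
    """Overflow or other numerical failure; message suggests a remedy."""
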