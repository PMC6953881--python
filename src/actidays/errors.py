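"""Exception hierarchy.

All errors derive from :class:`ActidaysError` so callers can catch the
package's failures with one clause; each also derives from the closest
builtin (ValueError) so plain Python code behaves sensibly.
"""


class ActidaysError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ActidaysError, ValueError):
    """A configuration field is missing, unknown, or outside its domain."""


class InputDataError(ActidaysError, ValueError):
    """An input recording, series, or matrix violates a precondition."""


class EmptySampleError(ActidaysError, ValueError):
    """No subject satisfies the analytical-sample filters."""


class ReliabilityDomainError(ActidaysError, ValueError):
    """Spearman-Brown prophecy requested for a non-positive reliability."""
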