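"""Exception hierarchy shared across the package.

All domain errors derive from :class:`SeeqrsError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` so they behave sanely in generic numeric code.
"""


class SeeqrsError(Exception):
    """Base class for all errors raised by seeqrs."""


class ParameterError(SeeqrsError, ValueError):
    """A configuration or argument value is outside its valid domain."""


class InputError(SeeqrsError, ValueError):
    """An input file or sequence is missing, empty, or unusable."""


class FormatError(InputError):
    """An input file exists but its content is malformed or inconsistent."""


class RangeError(InputError):
    """A requested segment or index lies outside the available data."""


class DegenerateSignalError(SeeqrsError, ValueError):
    """The signal is constant (e.g. flat-line) and the operation is undefined."""


class ReproductionMismatch(SeeqrsError):
    """A recomputed benchmark value disagrees with its published counterpart."""
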