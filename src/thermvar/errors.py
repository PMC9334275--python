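"""Exception hierarchy shared across the package.

All errors derive from :class:`ThermvarError` so callers (and the CLI) can
catch everything the library raises deliberately with one handler.
"""


class ThermvarError(Exception):
    """Base class for all deliberate errors raised by thermvar."""


class DomainError(ThermvarError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DesignError(ThermvarError, ValueError):
    """An input's structure cannot support the requested analysis
    (e.g. too few temperatures to identify a four-parameter curve)."""


class DataError(ThermvarError, ValueError):
    """A data table is internally inconsistent (impossible bookkeeping)."""
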