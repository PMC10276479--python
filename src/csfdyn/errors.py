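"""Exception hierarchy shared across the package."""


class CsfdynError(Exception):
    """Base class for all package errors."""


class FormatError(CsfdynError, ValueError):
    """An input file could not be parsed (malformed line, missing column)."""


class ContractError(CsfdynError, ValueError):
    """A precondition or invariant of an operation was violated."""


class UnusableTraceError(CsfdynError, ValueError):
    """A pressure trace is too corrupted to analyse (e.g. >50% masked)."""
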