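"""Exception hierarchy shared across the package."""


class CernaForgeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CernaForgeError, ValueError):
    """A caller-supplied argument violates a precondition."""


class FormatError(CernaForgeError, ValueError):
    """An on-disk file violates the expected format; message names the offender."""


class NumericError(CernaForgeError, RuntimeError):
    """A numerical routine failed (non-convergence, degenerate null, ...)."""


class ResourceError(CernaForgeError, RuntimeError):
    """A computation exceeded a configured budget (e.g. clique enumeration)."""
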