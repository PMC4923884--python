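"""Exception hierarchy shared across the package."""


class ModulenetError(Exception):
    """Base class for all package-specific errors."""


class DataError(ModulenetError):
    """Malformed or inconsistent input data (parse failures, invariant violations)."""


class ConvergenceError(ModulenetError):
    """A numerical solver failed in a way that yields no usable estimate."""


class NoSeedSetError(ModulenetError):
    """The network admits no seed-module set; the penalty must be re-tuned."""
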