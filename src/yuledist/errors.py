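"""Exception types shared across the package."""


class YuleDistError(Exception):
    """Base class for all yuledist errors."""


class ParameterError(YuleDistError, ValueError):
    """A model or configuration parameter violates its contract."""


class ContractError(YuleDistError, ValueError):
    """An operation was called outside its domain (e.g. unsupported statistic kind)."""


class FormatError(YuleDistError, ValueError):
    """An input file does not conform to the expected dialect."""


class ExplosionError(YuleDistError, RuntimeError):
    """The simulated lineage count exceeded the configured cap."""

    def __init__(self, cap: int):
        self.cap = cap
        super().__init__(
            f"simulation exceeded the lineage cap of {cap} alive lineages; "
            f"e^((lambda-mu)T) is too large for desk-scale simulation"
        )


class NonConvergenceError(YuleDistError, RuntimeError):
    """Raised only by the CLI when a fit did not converge (library flags instead)."""
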