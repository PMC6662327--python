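"""Exception hierarchy shared across the package."""


class PopGenError(ValueError):
    """Base class for all domain errors raised by popgenlab."""


class DomainError(PopGenError):
    """An input lies outside its mathematical domain (e.g. a frequency not in [0, 1])."""


class DegenerateModelError(PopGenError):
    """A model parameterisation makes the dynamic undefined (e.g. mean fitness zero)."""


class AllOneSexError(DegenerateModelError):
    """The population mean sex ratio hit 0 or 1, so sex-allocation fitness is undefined."""


class InvalidBaselineError(DegenerateModelError):
    """A game payoff plus baseline produced a non-positive fitness."""


class NotCoalescedError(PopGenError):
    """A sample has no single common ancestor within the simulated window."""


class SelectionTooStrongError(PopGenError):
    """Truncation selection left fewer than two parents."""


class FrameMismatchError(PopGenError):
    """Animation frames do not share identical dimensions."""


class ConfigError(PopGenError):
    """A run configuration file contains unknown or unparseable entries."""


class ParameterError(PopGenError):
    """A parameter failed validation; carries the offending parameter's name."""

    def __init__(self, param: str, message: str):
        self.param = param
        super().__init__(f"invalid value for parameter '{param}': {message}")
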