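class ThermoclockError(Exception):
    """Base class for all package errors."""


class DomainError(ThermoclockError):
    """A model quantity left its admissible domain (e.g. a concentration in a
    denominator reached zero)."""


class SimulationError(ThermoclockError):
    """Numerical integration failed or produced an inadmissible state."""


class ScheduleError(ThermoclockError):
    """Invalid temperature schedule or evaluation outside its domain."""


class ConfigError(ThermoclockError):
    """Configuration file failed validation.

    ``problems`` lists every violation found, not just the first.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
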