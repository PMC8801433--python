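"""Exception types shared across the pipeline stages."""


class RelapseTrackError(Exception):
    """Base class for all package errors."""


class ConfigError(RelapseTrackError):
    """Invalid configuration.

    Carries a list of human-readable messages so that a validator can
    report every problem at once rather than failing on the first.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class ValidationError(RelapseTrackError):
    """Invalid data passed to an operation (out-of-range item, bad seat number...)."""


class SimulationError(RelapseTrackError):
    """The simulator cannot produce a value (e.g. non-positive Weibull scale)."""


class ModelError(RelapseTrackError):
    """A model fit cannot proceed or produced an unusable result."""
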