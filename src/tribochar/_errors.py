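"""Exception and warning types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range (e.g. non-positive)."""


class IntegrationFailureError(RuntimeError):
    """The trajectory integrator produced a non-finite state."""


class SimulationTimeoutError(RuntimeError):
    """Every released particle exceeded the residence-time budget."""


class DegenerateNormalizationError(ValueError):
    """A feature is constant on the training set, so min-max scaling is undefined."""


class UncharacterizableError(ValueError):
    """Charge inversion is impossible: no collisions or zero contact area."""


class FullyDevelopedFlowWarning(UserWarning):
    """Pipe too short for the fully-developed-profile assumption (L/D < 10)."""


class RegimeWarning(UserWarning):
    """Requested flow regime is inconsistent with the Reynolds number."""


class RangeWarning(UserWarning):
    """An input lies outside the range the surrogate database covers."""


class DiluteLoadingWarning(UserWarning):
    """Solids volume fraction too high for strict one-way coupling."""


class ExtrapolationWarning(UserWarning):
    """A point maps outside [0, 1] under the training-set min-max state."""
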