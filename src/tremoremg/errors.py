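"""Exception hierarchy.

All package-specific failures derive from :class:`TremorError` so callers
can distinguish usage/contract problems from data problems at one catch
site (the CLI maps them to exit codes).
"""


class TremorError(Exception):
    """Base class for all tremoremg errors."""


class ParameterError(TremorError, ValueError):
    """Invalid parameter value (filter band, synthesis settings, ...)."""


class ContractError(TremorError, ValueError):
    """An operation was called on an object violating its preconditions
    (wrong processing stage, out-of-range phase, ...)."""


class DataError(TremorError):
    """Input data violates the data model (non-finite samples, ...)."""


class FormatError(DataError):
    """A file could not be parsed as the declared format."""


class RoleMappingError(DataError):
    """Channels could not be resolved to extensor/flexor roles."""


class InsufficientDataError(DataError):
    """Recording too short (or too few pairs) for the requested estimate."""


class NoTremorDetectedError(TremorError):
    """Spectral peak quality below the detection floor: no rhythmic
    tremor component found in the analysis band."""

    def __init__(self, peak_quality: float, floor: float):
        self.peak_quality = peak_quality
        self.floor = floor
        super().__init__(
            f"no tremor detected: peak quality {peak_quality:.3g} "
            f"below floor {floor:.3g}"
        )


class UndefinedPhaseError(TremorError):
    """Spectral magnitude at the tremor frequency is numerically zero in
    one channel, so its phase is undefined."""


class DegenerateDataError(DataError):
    """Statistic undefined on this input (zero variance, ...)."""
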