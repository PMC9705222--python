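"""Exception hierarchy for quadcal.

All package-specific failures derive from :class:`QuadcalError`.  The CLI maps
:class:`ConfigError` to exit code 2 and every other :class:`QuadcalError`
(including the :class:`DataError` family) to exit code 3.
"""


class QuadcalError(Exception):
    """Base class for all quadcal errors."""


class ConfigError(QuadcalError):
    """Invalid, unknown, or inconsistent configuration."""


class DataError(QuadcalError):
    """Input data violates a contract of the operation."""


class InvalidSizeError(DataError):
    """Sample or batch count below the supported minimum."""


class DegeneratePortError(DataError):
    """Balanced port pair cancels exactly; no interference envelope remains."""


class DepthRangeError(DataError):
    """Reflector placed outside the unambiguous depth range (-pi/2, pi/2)."""


class ShapeMismatchError(DataError):
    """Array shapes of two operands do not agree."""


class AveragingError(DataError):
    """No dominant spectral peak; coherent averaging cannot lock a phase."""


class DCOffsetError(DataError):
    """Residual DC too large for a meaningful analytic representation."""


class DivisionGuardError(DataError):
    """Denominator amplitude vanishes; amplitude ratio undefined."""


class AmbiguousPeakError(DataError):
    """More than one non-adjacent candidate peak within 3 dB of the maximum."""


class WeakPeakError(DataError):
    """Main peak not sufficiently above the noise floor for peak metrics."""


class UnderdeterminedError(DataError):
    """Fewer trusted samples than degrees of freedom of the requested fit."""


class CoverageError(DataError):
    """Calibration depths do not cover both sides of zero-delay."""


class NoUsableDepthsError(DataError):
    """Every depth was excluded; chromatic averaging has no input."""


class GaugeError(DataError):
    """Spatial correction vectors are not gauge-normalized at zero-delay."""


class IllConditionedError(DataError):
    """|sin(dphi)| below the conditioning threshold; reconstruction unstable."""


class GridMismatchError(DataError):
    """Operands were produced for different sample counts N."""
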