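"""Exception hierarchy for the hscompare pipeline.

All errors derive from :class:`HscompareError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin (ValueError / IndexError / OSError) so generic
call sites behave sensibly.
"""


class HscompareError(Exception):
    """Base class for all hscompare errors."""


class CoverageError(HscompareError, ValueError):
    """A requested wavelength grid is not covered by a reference table."""


class GeometryError(HscompareError, ValueError):
    """Scene / sensor / ROI geometry is inconsistent or too small."""


class ShapeError(HscompareError, ValueError):
    """Array shapes of related inputs do not match."""


class DegenerateReferenceError(HscompareError, ValueError):
    """White and dark references coincide (zero calibration denominator)."""


class EmptySelectionError(HscompareError, ValueError):
    """A band / wavelength selection retained nothing."""


class UnderdeterminedError(HscompareError, ValueError):
    """A regression problem has fewer observations than unknowns."""


class InsufficientBandsError(HscompareError, ValueError):
    """Too few usable bands to compute a spectral metric."""


class MetadataError(HscompareError, ValueError):
    """A file header is missing required metadata."""


class SizeMismatchError(HscompareError, OSError):
    """Binary payload size disagrees with the header geometry."""
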