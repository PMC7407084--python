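"""Exception types shared across osmofit modules."""


class OsmofitError(Exception):
    """Base class for all osmofit errors."""


class ParameterError(OsmofitError, ValueError):
    """Invalid simulation or analysis parameters."""


class DataError(OsmofitError, ValueError):
    """Malformed or physically impossible input data."""


class AlignmentError(OsmofitError, ValueError):
    """Replicate curves cannot be placed on a common time grid."""


class OutOfRangeError(OsmofitError, ValueError):
    """A query point lies outside the observed range."""


class EmptyCurveError(OsmofitError, ValueError):
    """No usable (above-floor) measurements in a curve or series."""


class NoCrossingError(OsmofitError, ValueError):
    """The evolved curve never reaches half its saturation OD."""


class DivisionGuardError(OsmofitError, ValueError):
    """Ancestor OD at T1/2 is at or below the measurement floor."""


class DegenerateShapeError(OsmofitError, ValueError):
    """A contour is too round or too distorted for rod morphometrics."""


class CoverageError(OsmofitError, ValueError):
    """A trajectory does not span the requested analysis window."""


class EmptyTableError(OsmofitError, ValueError):
    """An operation requiring records received an empty table."""
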