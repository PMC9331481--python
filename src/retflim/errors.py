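"""Exception hierarchy for retflim.

All package-raised errors derive from :class:`RetflimError` so callers can
catch one base type; subclasses name the failure mode the pipeline stages
report.
"""


class RetflimError(Exception):
    """Base class for all retflim errors."""


class InvalidGeometryError(RetflimError):
    """Phantom or section geometry is impossible (non-positive sizes,
    layers thicker than the section, disc outside tissue)."""


class ConfigurationError(RetflimError):
    """A configuration value is inconsistent (unknown tissue code, missing
    fluorophore channel, bad instrument parameters)."""


class InvalidInputError(RetflimError):
    """Input data violate a precondition (empty cube, malformed file)."""


class CalibrationError(RetflimError):
    """Phasor calibration cannot proceed (zero-intensity reference)."""


class DegenerateTrajectoryError(RetflimError):
    """Metabolic trajectory is undefined (center of mass coincides with the
    free-lifetime anchor, or the chord has zero length)."""


class EmptyResultError(RetflimError):
    """Every ROI or group was excluded; nothing to report."""


class SchemaError(RetflimError):
    """On-disk sidecar or configuration file fails schema validation."""
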