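"""Exception hierarchy for the esdm package."""


class EsdmError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(EsdmError):
    """Raster grids do not share shape or georeferencing."""


class FormatError(EsdmError):
    """An input file does not follow the expected layout."""


class EmptyDataError(EsdmError):
    """An operation received no usable rows/points/cells."""


class CollinearityError(EsdmError):
    """The feature table is unusable for VIF analysis (e.g. constant column)."""


class FitError(EsdmError):
    """A member algorithm failed to fit; carries the algorithm diagnostics."""


class NoSkillError(EsdmError):
    """No ensemble member has positive skill (TSS > 0)."""


class ConsistencyError(EsdmError):
    """An internal accounting identity was violated (threshold/mask bug)."""


class ConfigError(EsdmError):
    """Pipeline configuration failed validation."""
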