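"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`FloracastError` so callers can
distinguish pipeline failures from programming errors.
"""


class FloracastError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(FloracastError):
    """A configuration value violates a documented constraint."""


class InvalidExtentError(InvalidConfigError):
    """The requested grid extent contains zero cells."""


class InvalidParameterError(FloracastError):
    """A numeric parameter is outside its valid domain."""


class NoHabitatError(FloracastError):
    """Occurrence sampling was requested for a species with an empty range."""


class NoUsableRecordsError(FloracastError):
    """All occurrence records fall outside the model grid."""


class NoBackgroundError(FloracastError):
    """No cells are available for background sampling."""


class UndefinedAUCError(FloracastError):
    """AUC requested with an empty score set."""


class FitFailureError(FloracastError):
    """A learner could not be fitted; it is excluded from the ensemble."""


class UnmodelableSpeciesError(FloracastError):
    """No learner passed the AUC inclusion cutoff for this species."""


class ProjectionError(FloracastError):
    """A projection grid is missing a covariate the model needs."""


class InvalidLatitudeError(FloracastError):
    """Cell-area computation outside [-90, 90] latitude bounds."""


class UndefinedBaselineError(FloracastError):
    """Change classification with a zero current-period AOH."""


class NoCentroidError(FloracastError):
    """Centroid of an empty occupancy map."""


class AlignmentError(FloracastError):
    """Two rasters do not share the same grid."""


class UndefinedMSRError(FloracastError):
    """Mean species richness over an empty mask."""
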