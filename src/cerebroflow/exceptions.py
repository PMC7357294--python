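"""Exception and warning types shared across the toolkit."""


class CerebroflowError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(CerebroflowError):
    """A generator or paradigm specification violates its invariants."""


class CoverageError(CerebroflowError):
    """A regressor/trace does not cover the requested time window."""


class EmptyTraceError(CerebroflowError):
    """No end-tidal peaks could be extracted from a capnogram."""


class DegenerateDesignError(CerebroflowError):
    """The regression design has no usable variance (e.g. flat EtCO2)."""


class NormalizationError(CerebroflowError):
    """Percent normalisation impossible (zero mean signal)."""


class EmptyMaskError(CerebroflowError):
    """A voxel mask selects no voxels."""


class MissingStructureError(CerebroflowError):
    """A required vascular structure is absent from the waveform set."""


class MissingAreaError(CerebroflowError):
    """Background velocity given without an ROI area to convert it to flow."""


class DegenerateImageError(CerebroflowError):
    """Image statistics are degenerate (e.g. zero within-mask SD)."""


class TransformError(CerebroflowError):
    """A required transform is undefined for the given value (e.g. log of 0)."""


class MissingFeatureError(CerebroflowError):
    """A required visual-score component is missing."""


class MissingDataError(CerebroflowError):
    """Required clinical data are absent (e.g. no BP readings)."""


class NoVarianceError(CerebroflowError):
    """A modelled predictor is constant."""


class SingularDesignError(CerebroflowError):
    """The regression design matrix is rank deficient."""


class ConfigError(CerebroflowError):
    """Pipeline configuration failed validation."""


class StageDependencyError(CerebroflowError):
    """A pipeline stage's inputs are missing because an upstream stage is off."""


class WrongStructureWarning(UserWarning):
    """CSF dynamics requested on a non-CSF structure; computation proceeds."""


class CompletenessWarning(UserWarning):
    """Fewer observations than expected (e.g. <7 BP readings)."""
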