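"""Exception hierarchy shared across the package."""


class NcrusError(Exception):
    """Base class for all package-specific errors."""


class InvalidAnnotationError(NcrusError):
    """Mass annotations are physically inconsistent (e.g. turgid mass <= dry mass)."""


class ConfigurationError(NcrusError):
    """A configuration value is out of its admissible range or unknown."""


class AlignmentError(NcrusError):
    """Two spectra that must share a frequency grid do not."""


class IncompleteMeasurementError(NcrusError):
    """A measurement does not carry one spectrum per transducer band."""


class DataQualityError(NcrusError):
    """A spectrum's frequency support is too narrow for resampling."""


class DegenerateSpectrumError(NcrusError):
    """A spectrum carries no usable resonance structure (e.g. flat magnitude)."""


class IntegrityError(NcrusError):
    """Dataset bookkeeping is inconsistent (e.g. duplicate leaf identifiers)."""


class TrainingFailureError(NcrusError):
    """Model training produced non-finite loss; carries the offending config."""


class ModelStateError(NcrusError):
    """A model was used before it was trained."""
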