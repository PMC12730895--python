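"""Exception hierarchy.

Every reader, fitter and scorer raises a subclass of :class:`MotiscoreError`;
nothing is silently coerced or imputed.
"""


class MotiscoreError(Exception):
    """Base class for all package errors."""


class FormatError(MotiscoreError):
    """A file does not conform to its expected dialect (named column/line)."""


class VocabularyError(FormatError):
    """A value is outside its controlled vocabulary (e.g. impact labels)."""


class IntegrityError(MotiscoreError):
    """Internally inconsistent data: duplicate ids, negative counts,
    tampered model files."""


class ConfigurationError(MotiscoreError):
    """Missing or invalid configuration (thresholds, metrics, column maps)."""


class DataConsistencyError(MotiscoreError):
    """Cross-input mismatch, e.g. a neoantigen restricted to an HLA allele
    absent from the genotype."""


class AlignmentError(MotiscoreError):
    """Aligned sequences of unequal length where equality is required."""


class FittingError(MotiscoreError):
    """Model fitting is impossible (constant biomarker, no selected features)."""


class ScoringError(MotiscoreError):
    """A sample cannot be scored (missing selected biomarker, unset cutoff)."""


class EvaluationError(MotiscoreError):
    """An evaluation statistic is undefined for the given inputs."""


class DegenerateDataError(EvaluationError):
    """Estimation would be silently meaningless: no events in a group,
    monotone Cox partial likelihood (complete separation)."""
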