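"""Exception hierarchy for the reefhdr pipeline.

ConfigurationError signals caller mistakes (bad schema, unknown labels);
DataError signals unusable input; the remaining classes mark per-group
degeneracies that callers typically log and skip rather than abort on.
"""


class ReefHDRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ReefHDRError):
    """A schema, formula, or scenario configuration problem."""


class DataError(ReefHDRError):
    """Input data is missing or structurally unusable."""


class DegenerateGradientError(ReefHDRError):
    """Heterogeneity values have zero variance; no gradient to standardize."""


class UndefinedCVError(ReefHDRError):
    """Coefficient of variation is undefined (non-positive mean)."""


class BaselineUndefinedError(ReefHDRError):
    """The lnRR baseline mean is zero; ratios are undefined."""


class ModelFitError(ReefHDRError):
    """A mixed-model fit could not be carried out (insufficient grouping,
    non-convergence after restarts)."""
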