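"""Exception hierarchy shared across the package."""


class PhenofuseError(Exception):
    """Base class for all package-specific errors."""


class InputError(PhenofuseError, ValueError):
    """Malformed or inconsistent user input (files, tables, counts)."""


class UndefinedSimilarityError(PhenofuseError, ValueError):
    """A pairwise similarity is mathematically undefined (zero norm / zero variance)."""


class DegenerateDispersionError(PhenofuseError, ValueError):
    """The dispersion of raw scores is zero, so the exponential transform is undefined."""


class DegeneratePredictorError(PhenofuseError, ValueError):
    """The genotype-similarity predictor has zero variance; the slope test is undefined."""


class CalibrationUnavailableError(PhenofuseError, ValueError):
    """An empty null sample was supplied for empirical p-value calibration."""
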