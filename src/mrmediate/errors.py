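"""Exception hierarchy for the MR workflow."""


class MRMediateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MRMediateError):
    """A required column is absent from an input summary-statistics table."""


class EmptyPairError(MRMediateError):
    """Exposure and outcome share no variants (or none survive harmonization)."""


class ConfigurationError(MRMediateError):
    """Inconsistent inputs, e.g. a candidate variant missing from the LD matrix."""


class DegenerateInstrumentError(MRMediateError):
    """All instruments have zero exposure effect; the Wald ratio is undefined."""


class InsufficientInstrumentsError(MRMediateError):
    """Fewer variants than the estimator or diagnostic requires."""


class CollinearityError(MRMediateError):
    """Rank-deficient exposure design in multivariable MR."""

    def __init__(self, exposure_names):
        self.exposure_names = list(exposure_names)
        super().__init__(
            "rank-deficient MVMR design; collinear exposures among: "
            + ", ".join(self.exposure_names)
        )


class ValueUnavailableError(MRMediateError):
    """A quantity (EAF, N) needed for the computation is missing."""
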