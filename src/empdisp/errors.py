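"""Exception types shared across the package."""


class EmpdispError(Exception):
    """Base class for package errors."""


class InvalidScenarioError(EmpdispError):
    """A synthetic scenario violates its preconditions."""


class InvalidForcingError(EmpdispError):
    """A growth-rate forcing is unusable (e.g. worst-case rate is not negative)."""


class ForcingGapError(EmpdispError):
    """The forcing matrix does not cover the requested projection years."""

    def __init__(self, missing_years):
        self.missing_years = list(missing_years)
        super().__init__(
            f"forcing does not cover projection years: {self.missing_years}"
        )


class SamplingAtExtinctColonyError(EmpdispError):
    """A sampling design point hits a colony with (numerically) zero abundance."""

    def __init__(self, colony_id, year):
        self.colony_id = colony_id
        self.year = year
        super().__init__(
            f"cannot sample colony {colony_id!r} in year {year}: abundance is zero"
        )


class NoLociSurviveError(EmpdispError):
    """All loci were removed by the presence / polymorphism filters."""


class DegeneratePosteriorError(EmpdispError):
    """Every importance draw has zero likelihood; the posterior is undefined."""


class SchemaError(EmpdispError):
    """A delimited input file violates its schema."""
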