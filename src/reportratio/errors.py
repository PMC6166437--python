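"""Exception hierarchy for the paired-mode reporting analysis."""


class ReportRatioError(Exception):
    """Base class for all package errors."""


class CodingError(ReportRatioError):
    """An outcome or demographic code is outside its category set."""


class UnsupportedWindowError(ReportRatioError):
    """A recall window was requested that the survey round cannot support."""


class UnsupportedRoundError(ReportRatioError):
    """An analysis was requested for a round whose instruments cannot supply it."""


class MissingModeError(ReportRatioError):
    """A respondent lacks one of the two interview modes (or refused an item)."""


class SchemaError(ReportRatioError):
    """Input file does not match the declared column schema."""


class CohortError(ReportRatioError):
    """Cohort-level invariant violated (e.g. mixed survey rounds)."""


class OrphanRecordError(ReportRatioError):
    """A pregnancy event row references a respondent id that does not exist."""


class UndefinedRatioError(ReportRatioError):
    """A reporting ratio has a zero denominator (no FTF reporters)."""


class NoReplicatesError(ReportRatioError):
    """A percentile was requested from an empty replicate sequence."""


class DegenerateBootstrapError(ReportRatioError):
    """Too many bootstrap replicates had an undefined (zero-denominator) ratio."""


class IncompatibleBootstrapError(ReportRatioError):
    """Two bootstrap results cannot be differenced (unequal replicate counts)."""


class UndefinedProportionError(ReportRatioError):
    """A proportion was requested over an empty discordant set."""


class RenderingError(ReportRatioError):
    """Inconsistent result set passed to a table renderer."""


class ConfigError(ReportRatioError):
    """Invalid run or generator configuration."""
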