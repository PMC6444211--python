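"""Exception hierarchy for the eship2 package."""


class Eship2Error(Exception):
    """Base class for all package-specific errors."""


class ReadingError(Eship2Error, ValueError):
    """A measurement triple violates a physical or device-range constraint."""


class ScheduleError(Eship2Error, ValueError):
    """A session's slot layout or device-source tags violate the protocol schedule."""


class GradingError(Eship2Error, ValueError):
    """Band counts and requirement table are incompatible, or counts are malformed."""


class EligibilityError(Eship2Error, ValueError):
    """The cohort fails the protocol's recruitment requirements and grading was not forced."""


class ConfigError(Eship2Error, ValueError):
    """A simulation configuration is internally inconsistent."""


class CsvFormatError(Eship2Error, ValueError):
    """A session CSV is malformed; message names the offending row/column."""
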