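"""Exception hierarchy.

CLI exit codes: configuration problems exit 2, data problems exit 3.
"""


class FetalVolError(Exception):
    """Base class for all package errors."""

    exit_code = 3


class VolumeFormatError(FetalVolError):
    """A volume/mask file could not be read or lacks required metadata."""


class AlignmentError(FetalVolError):
    """A mask does not align with the volume it annotates."""


class SpecificationError(FetalVolError):
    """An invalid phantom or study specification (e.g. overlapping organs)."""

    exit_code = 2


class RefinementError(FetalVolError):
    """Border refinement cannot run (e.g. empty input segment)."""


class DegenerateDataError(FetalVolError):
    """A statistic is undefined for the given data (zero variance, n too small)."""


class ConfigError(FetalVolError):
    """Invalid YAML study configuration."""

    exit_code = 2
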