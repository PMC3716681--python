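"""Named exceptions raised by the pipeline.

Every degenerate input fails loudly with one of these instead of silently
emitting copy number 0 or an empty report.
"""


class RdcnvError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RdcnvError, ValueError):
    """A simulation or run configuration value is out of range or inconsistent."""


class PlacementError(RdcnvError, RuntimeError):
    """A simulated annotation or truth event could not be placed without overlap."""


class BaselineUnstableError(RdcnvError, RuntimeError):
    """Too few supporting bins to estimate the diploid depth baseline."""


class RefinementFailedError(RdcnvError, RuntimeError):
    """The genome-wide diploid-bin prediction returned an empty set."""


class EstimationError(RdcnvError, RuntimeError):
    """Copy-number estimation hit a fatal condition (e.g. non-positive baseline)."""


class UndefinedStatisticError(RdcnvError, ValueError):
    """A statistic is undefined for the given input (e.g. s.d. over < 2 samples)."""


class FileFormatError(RdcnvError, ValueError):
    """A malformed input file; the message names the file and line number."""
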