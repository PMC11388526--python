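"""Exception hierarchy for denitscan.

Every error raised on a user-facing path derives from :class:`DenitscanError`
so the CLI can catch one type and report the failing stage.
"""


class DenitscanError(Exception):
    """Base class for all denitscan errors."""


class FormatError(DenitscanError):
    """A sequence or annotation file violates its format contract."""


class AlignmentError(FormatError):
    """A multiple sequence alignment is malformed (e.g. ragged rows)."""


class BuildError(DenitscanError):
    """Profile construction failed (e.g. no column passes occupancy)."""


class CalibrationError(DenitscanError):
    """Trusted-cutoff calibration failed because the score sets overlap."""

    def __init__(self, message, overlaps=None):
        super().__init__(message)
        #: list of (set_name, sequence_id, bit_score) for offending sequences
        self.overlaps = overlaps or []


class ConfigError(DenitscanError):
    """A registry configuration file is invalid."""


class SearchError(DenitscanError):
    """Proteome search preconditions violated (e.g. uncalibrated model)."""


class ClusterError(DenitscanError):
    """Nos-gene-cluster reconstruction received inconsistent inputs."""


class SimulationError(DenitscanError):
    """Synthetic-data generation received degenerate parameters."""
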