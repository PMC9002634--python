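"""Exception hierarchy shared across the package."""


class TendonMetricsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TendonMetricsError):
    """A domain object violates one of its invariants."""


class LoadError(TendonMetricsError):
    """A session/trial could not be read from disk."""


class ConfigError(TendonMetricsError):
    """A generator or analysis configuration is invalid."""


class SynchronizationError(TendonMetricsError):
    """A stream cannot be placed on the common time base."""


class FlatImageError(TendonMetricsError):
    """Correlation is undefined because template or window has zero variance."""


class TrackingLostError(TendonMetricsError):
    """The tracked feature left the search window.

    ``last_good_frame`` is the index of the last frame with a confident match.
    """

    def __init__(self, message: str, last_good_frame: int):
        super().__init__(message)
        self.last_good_frame = last_good_frame


class StatsError(TendonMetricsError):
    """A statistic is undefined for the given data (degenerate input)."""
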