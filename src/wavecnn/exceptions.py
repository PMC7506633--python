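"""Exception types shared across the package."""


class WavecnnError(Exception):
    """Base class for all package-specific errors."""


class InputError(WavecnnError, ValueError):
    """Invalid input data (empty arrays, mismatched lengths, bad labels)."""


class DimensionError(WavecnnError, ValueError):
    """Array dimensions incompatible with the requested operation."""


class ShapeError(WavecnnError, ValueError):
    """Layer-graph shape propagation failure (e.g. concat size mismatch)."""


class AuditError(WavecnnError, ValueError):
    """Parameter audit encountered an unknown or malformed layer."""


class UndefinedMetricError(WavecnnError, ValueError):
    """A metric's denominator is zero, so the value is undefined."""


class ConfigError(WavecnnError, ValueError):
    """Invalid training configuration or empty data manifest."""


class DivergenceError(WavecnnError, RuntimeError):
    """Training loss became non-finite; carries the epoch index."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
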