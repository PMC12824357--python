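"""Exception hierarchy shared across the package.

Every validation failure raises a named subclass of :class:`HiergradError`
so callers (and the study orchestrator) can attribute failures to a stage.
"""


class HiergradError(Exception):
    """Base class for all package errors."""


class FormatError(HiergradError):
    """A file or table violates its documented format."""


class ShapeError(HiergradError):
    """Array dimensions disagree with the atlas or with each other."""


class DegenerateDataError(HiergradError):
    """Data are formally valid but carry no usable signal (constant rows,
    zero-variance targets, rows without positive edges, ...)."""


class ConnectivityError(HiergradError):
    """The affinity graph is disconnected; diffusion embedding is refused."""


class ConfigError(HiergradError):
    """A configuration value is out of its documented domain."""


class ModelError(HiergradError):
    """A statistical model cannot be fit (singular design, collinearity)."""


class FitError(HiergradError):
    """A kinetic-model fit failed (all bases singular, no valid frames)."""


class GeometryError(HiergradError):
    """Spherical geometry is unavailable (no cortical centroids)."""


class StageError(HiergradError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
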