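"""Exception hierarchy for the tlstree pipeline.

Every stage raises a subclass of :class:`TlsTreeError` so callers can trap
pipeline failures distinctly from programming errors.
"""


class TlsTreeError(Exception):
    """Base class for all tlstree errors."""


class ParameterError(TlsTreeError, ValueError):
    """Invalid parameter value (e.g. non-positive point spacing)."""


class ParseError(TlsTreeError):
    """Malformed point-cloud file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"{message} (line {line})")


class EmptyInputError(TlsTreeError):
    """An operation received an empty cloud / record set."""


class InsufficientPointsError(TlsTreeError):
    """Too few points in a cross-section slab for a stable fit."""


class FitDegenerateError(TlsTreeError):
    """Degenerate geometry (e.g. collinear points) for a circle fit."""


class DegenerateAlphaError(TlsTreeError):
    """Alpha shape is empty or fragmented beyond use at the given alpha."""


class DisconnectedCloudError(TlsTreeError):
    """Point cloud is not connected at the chosen neighbourhood radius."""

    def __init__(self, n_components: int, orphan_fraction: float):
        self.n_components = n_components
        self.orphan_fraction = orphan_fraction
        super().__init__(
            f"cloud splits into {n_components} components "
            f"({orphan_fraction:.1%} of points outside the largest)"
        )


class PlacementError(TlsTreeError):
    """Could not place trees in a plot without trunk overlap."""


class ConfigError(TlsTreeError):
    """Invalid or incomplete configuration (pipeline or model bank)."""


class PredictorError(TlsTreeError):
    """An allometric model is missing a predictor it requires."""


class PairingError(TlsTreeError):
    """Tree ids of two per-tree tables cannot be matched one-to-one."""


class EnsembleError(TlsTreeError):
    """All runs of a QSM ensemble failed."""
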