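"""Exception hierarchy shared across laminarkit."""


class LaminarkitError(Exception):
    """Base class for all laminarkit errors."""


class MeshError(LaminarkitError):
    """Invalid surface mesh (bad indices, degenerate edges, disconnected graph)."""


class NoPathError(LaminarkitError):
    """No geodesic path exists between the requested seed vertices."""


class RoiTooNarrowError(LaminarkitError):
    """ROI cannot host the requested number of parallel paths."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"ROI too narrow for {requested} paths; at most {achievable} achievable"
        )


class NoLaminarStructureError(LaminarkitError):
    """Depth profile has no interior derivative extrema (e.g. strictly linear)."""


class NormalizationError(LaminarkitError):
    """Profile has zero range; min-max normalization undefined."""


class OverlayMissingError(LaminarkitError):
    """A required named overlay is absent from the mesh."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"required overlay {name!r} is missing")


class DesignError(LaminarkitError):
    """Inconsistent phase-encoded design arithmetic (durations vs TR)."""


class StaircaseError(LaminarkitError):
    """Staircase log unusable (e.g. no reversal inside the scoring window)."""
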