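"""Exception hierarchy shared across the package."""


class ShadowCwsiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ShadowCwsiError, ValueError):
    """Invalid argument or inconsistent input metadata."""


class InsufficientMatchesError(ShadowCwsiError):
    """Too few keypoint matches to proceed."""

    def __init__(self, count: int, minimum: int = 3):
        self.count = count
        self.minimum = minimum
        super().__init__(
            f"found {count} matches, need at least {minimum}"
        )


class DegenerateGeometryError(ShadowCwsiError):
    """Point configuration cannot constrain the requested transform."""


class NoConsensusError(ShadowCwsiError):
    """RANSAC failed to find a consensus set of minimal size."""


class DegenerateHistogramError(ShadowCwsiError):
    """Temperature histogram has no spread; reference temps undefined."""
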