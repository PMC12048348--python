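"""Exception hierarchy for the sedlab pipeline."""


class SedlabError(Exception):
    """Base class for all sedlab errors."""


class FormatError(SedlabError, ValueError):
    """Container lacks a 4D signal or violates the documented layout."""


class DataError(SedlabError, ValueError):
    """Counts are non-finite or otherwise unusable."""


class CenteringError(SedlabError, RuntimeError):
    """Direct-beam localisation failed for one or more scan positions."""

    def __init__(self, positions, message="direct-beam correlation below significance"):
        self.positions = list(positions)
        super().__init__(f"{message} at scan positions {self.positions[:10]}"
                         + ("..." if len(self.positions) > 10 else ""))


class RefinementError(SedlabError, RuntimeError):
    """Centre-of-mass refinement is undefined (zero or flat window)."""


class TraceError(SedlabError, RuntimeError):
    """Bend-contour ridge tracing failed (seed on background, ridge lost)."""


class GeometryError(SedlabError, RuntimeError):
    """Traced centerlines do not intersect the dislocation line."""


class FitRefusedError(SedlabError, RuntimeError):
    """Displacement profile is under-constrained for the azimuthal fit."""


class EmptyProfileError(SedlabError, ValueError):
    """No usable bend-contour crossings."""


class NoResolvableDistortion(SedlabError, RuntimeError):
    """All displacements consistent with zero; Burgers azimuth undefined."""
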