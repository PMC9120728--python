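"""Exception hierarchy.

Every validation failure raises a distinct subclass of :class:`AtrophyNetError`
so callers (and the CLI) can map failures to actionable messages; silent
coercion of invalid inputs is never performed.
"""


class AtrophyNetError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(AtrophyNetError):
    """A point that should lie on the unit sphere does not."""


class InvalidMeshError(AtrophyNetError):
    """Mesh topology is malformed (degenerate face, disconnected patch, ...)."""


class InvalidParameterError(AtrophyNetError):
    """A numeric parameter is outside its admissible range."""


class UndefinedRegionError(AtrophyNetError):
    """A parcellation region has no assigned vertices (or an unknown id)."""


class DesignError(AtrophyNetError):
    """The GLM design matrix is unusable (rank deficiency, bad columns)."""


class MissingDataError(DesignError):
    """Covariate or outcome values required by a design are missing."""


class InvalidConnectomeError(AtrophyNetError):
    """Connectivity matrix violates symmetry / diagonal / range invariants."""


class UndefinedCorrelationError(AtrophyNetError):
    """Pearson correlation requested against a constant map."""


class ConfigurationError(AtrophyNetError):
    """Mismatched analysis metadata or an invalid run configuration."""


class LoadError(AtrophyNetError):
    """An input file violates a type invariant; message cites the location."""
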