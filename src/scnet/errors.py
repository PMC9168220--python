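"""Exception hierarchy for the scnet pipeline."""


class ScnetError(Exception):
    """Base class for all scnet errors."""


class ConfigurationError(ScnetError):
    """Invalid generator or pipeline configuration."""


class DegenerateDesignError(ScnetError):
    """Confound design matrix is rank deficient.

    Carries the name(s) of the offending column(s) so the user can see at a
    glance which covariate has no variation (e.g. a single-gender group).
    """

    def __init__(self, columns, message=None):
        self.columns = tuple(columns)
        super().__init__(
            message
            or f"degenerate confound design; offending column(s): {', '.join(self.columns)}"
        )


class ZeroVarianceRegionError(ScnetError):
    """A region has zero variance across subjects; its correlations are undefined."""

    def __init__(self, region, message=None):
        self.region = region
        super().__init__(message or f"region {region!r} has zero variance across subjects")


class AlignmentError(ScnetError):
    """Subject or region identifiers of two tables do not line up."""


class DensityInfeasibleError(ScnetError):
    """Requested graph density exceeds the supply of positive edges."""

    def __init__(self, requested, max_density, message=None):
        self.requested = requested
        self.max_density = max_density
        super().__init__(
            message
            or (
                f"density {requested:.4f} infeasible: only enough positive edges "
                f"for density {max_density:.4f}"
            )
        )


class DisconnectedGraphError(ScnetError):
    """A graph that must be fully connected is not."""


class TableFormatError(ScnetError):
    """A tabular input file does not match the expected layout."""
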