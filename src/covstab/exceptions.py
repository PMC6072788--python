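"""Exception and warning types shared across the package."""


class CovstabError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CovstabError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class RankDeficiencyError(CovstabError, ValueError):
    """A covariate design matrix is rank deficient (e.g. a constant column)."""


class ZeroVarianceError(CovstabError, ValueError):
    """A region has zero variance in a subject subset, so Pearson r is undefined."""


class DisconnectedGraphError(CovstabError, ValueError):
    """Characteristic path length requested on a graph with unreachable node pairs."""


class DegeneratePermutationError(CovstabError, RuntimeError):
    """Too many consecutive degenerate permutation splits (zero-variance region)."""


class NegativeEdgeWarning(UserWarning):
    """Binarization at the requested density retained a non-positive correlation."""
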