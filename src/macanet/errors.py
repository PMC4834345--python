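"""Exception hierarchy for macanet.

All domain errors derive from :class:`MacanetError` so callers can catch
everything the library raises with a single except clause.
"""


class MacanetError(Exception):
    """Base class for all macanet errors."""


class StructureError(MacanetError):
    """An interaction matrix file is not a square named matrix."""


class ConsistencyError(MacanetError):
    """Matrix and attribute table disagree about the id universe."""


class DegenerateNetworkError(MacanetError):
    """The network has no ties, so the requested statistic is undefined."""


class DegenerateAttributeError(MacanetError):
    """The attribute vector is constant, so autocorrelation is undefined."""


class DegenerateGroupError(MacanetError):
    """A categorical level has too few members for a group comparison."""


class DesignError(MacanetError):
    """The regression design matrix is rank deficient or under-sized."""


class ConfigError(MacanetError):
    """A generator configuration is internally inconsistent."""


class PipelineError(MacanetError):
    """A protocol stage failed; the message names the stage."""
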