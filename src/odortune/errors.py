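"""Exception hierarchy for the odortune pipeline.

All errors derive from :class:`OdortuneError` so callers can catch the
package's failures with a single except clause; the granular subclasses
name the contract that was violated.
"""


class OdortuneError(Exception):
    """Base class for all odortune errors."""


class InvalidParameterError(OdortuneError, ValueError):
    """A numeric parameter violated its domain (e.g. fold <= 1, c < 0)."""


class ConsistencyError(OdortuneError, ValueError):
    """A plate layout refers to a receptor/ligand absent from the truth."""


class MalformedTraceError(OdortuneError, ValueError):
    """A trace lacks the samples required for a window computation."""


class NormalizationError(OdortuneError, ValueError):
    """A plate is missing the control condition needed to normalize."""


class DegenerateControlError(NormalizationError):
    """The positive control's maximum response is non-positive."""


class InsufficientDataError(OdortuneError, ValueError):
    """Too few points/replicates to perform a fit or summary."""


class UndefinedSparsenessError(OdortuneError, ValueError):
    """Lifetime sparseness is 0/0: every zeroed response is zero."""


class ComparisonError(OdortuneError, ValueError):
    """Group comparison received fewer than two groups or replicates."""


class AlignmentError(OdortuneError, ValueError):
    """Tuning profiles do not share the same ligand panel."""


class StageOrderError(OdortuneError, RuntimeError):
    """A pipeline stage ran before its prerequisite outputs exist."""


class ConfigError(OdortuneError, ValueError):
    """Pipeline configuration failed validation."""
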