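"""Exception hierarchy shared across modules."""


class IslandTraitsError(Exception):
    """Base class for all package errors."""


class NewickParseError(IslandTraitsError):
    """Malformed Newick input (offending position reported when known)."""


class MissingBranchLengthError(NewickParseError):
    """A non-root edge lacks a branch length; no silent default is applied."""


class InvalidTreeError(IslandTraitsError):
    """Tree violates a structural invariant (negative length, duplicate tip...)."""


class NotUltrametricError(IslandTraitsError):
    """An operation requiring a time-calibrated ultrametric tree got one that is not."""


class DataError(IslandTraitsError):
    """Malformed or inconsistent tabular input."""


class FitError(IslandTraitsError):
    """Model fitting failed (underdetermined data, non-convergence...)."""
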