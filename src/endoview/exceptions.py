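"""Exception hierarchy for endoview."""


class EndoviewError(Exception):
    """Base class for all endoview errors."""


class DegenerateGeometryError(EndoviewError):
    """Point configuration (collinear/coincident) cannot constrain a transform."""


class InsufficientPointsError(EndoviewError):
    """Fewer correspondences than the estimator requires."""


class ValidationError(EndoviewError):
    """An input object violates its invariants (e.g. non-orthogonal rotation)."""


class NoIntersectionError(EndoviewError):
    """Parallel planes / line parallel to plane: the requested intersection
    does not exist."""


class DegenerateViewError(EndoviewError):
    """The projection surface lies behind the virtual viewpoint."""


class UnresolvedClickError(EndoviewError):
    """One or more clicked points could not be snapped to a feature that owns
    a map point.

    Attributes
    ----------
    indices : list of int
        Indices of the clicks that could not be resolved.
    """

    def __init__(self, indices, radius):
        self.indices = list(indices)
        self.radius = radius
        super().__init__(
            f"clicks {self.indices} have no feature with a map point "
            f"within {radius} px"
        )
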