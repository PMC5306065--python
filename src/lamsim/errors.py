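"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition."""


class ElementInversionError(RuntimeError):
    """One or more elements have non-positive Jacobian (det F <= 0).

    Carries the indices of the offending elements in ``elements``.
    """

    def __init__(self, message, elements=None):
        super().__init__(message)
        self.elements = elements


class NonConvergenceError(RuntimeError):
    """The nonlinear solve (fit or FE) failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PartialResultError(NonConvergenceError):
    """Quasi-static stepping failed partway; converged prefix is attached."""

    def __init__(self, message, states=None, diagnostics=None):
        super().__init__(message, diagnostics)
        self.states = states or []


class GimbalAmbiguityError(RuntimeError):
    """Euler decomposition at a gimbal-degenerate orientation.

    ``solutions`` holds the two angle triples consistent with the rotation.
    """

    def __init__(self, message, solutions=None):
        super().__init__(message)
        self.solutions = solutions


class UnknownLandmarkError(KeyError):
    """A named landmark or node set does not exist on the object."""


class GeometryError(RuntimeError):
    """Degenerate geometry (zero-area triangles, inverted cells, ...)."""
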