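"""Exception hierarchy shared across the package."""


class OstiaflowError(Exception):
    """Base class for all package errors."""


class ValidationError(OstiaflowError, ValueError):
    """An input value violates a documented invariant or precondition."""


class GeometryConflictError(ValidationError):
    """Two geometric primitives (e.g. coronary stubs) intersect."""


class MeshingError(OstiaflowError):
    """Tetrahedralization failed or produced a non-watertight mesh."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class ParameterError(ValidationError):
    """A parameter set (e.g. Carreau constants) violates its invariants."""


class FitError(OstiaflowError):
    """Nonlinear least-squares fit failed to converge."""

    def __init__(self, message, residual=None, params=None):
        super().__init__(message)
        self.residual = residual
        self.params = params


class ConfigurationError(OstiaflowError):
    """A run configuration is inconsistent with the mesh or missing keys."""


class SolverError(OstiaflowError):
    """The linear or nonlinear solve failed irrecoverably."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class StateError(OstiaflowError):
    """An operation was called before the state it needs exists."""


class RegionError(ValidationError):
    """A surface region descriptor selects no faces."""


class FormatError(OstiaflowError):
    """A mesh/solution file is malformed or has an unknown extension."""
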