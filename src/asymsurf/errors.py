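"""Exception hierarchy shared by all asymsurf modules."""


class AsymsurfError(Exception):
    """Base class for all package errors."""


class StructuralError(AsymsurfError):
    """Inputs are structurally incompatible (topology, vertex counts, spaces)."""


class ValidationError(AsymsurfError):
    """A file or table fails validation on load."""


class ConvergenceError(AsymsurfError):
    """An iterative procedure failed to converge."""
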