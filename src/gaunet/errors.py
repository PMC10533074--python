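"""Exception hierarchy shared across the package."""


class GAUNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GAUNetError, ValueError):
    """A search space, GA or dataset configuration is invalid."""


class GenomeError(GAUNetError, ValueError):
    """A genome is structurally broken or violates its search space."""


class ShapeError(GAUNetError, ValueError):
    """Array shapes are incompatible (masks, network inputs)."""


class IntegrityError(GAUNetError, ValueError):
    """A dataset directory is inconsistent (missing / mismatched files)."""


class StateError(GAUNetError, RuntimeError):
    """An operation was called before its prerequisites were established."""


class DivergenceError(GAUNetError, RuntimeError):
    """Training produced a non-finite loss."""
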