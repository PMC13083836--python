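"""Exception hierarchy shared across the package."""


class QwireError(Exception):
    """Base class for all package errors."""


class ParseError(QwireError):
    """A coordinate file could not be read under the named standard."""


class UsageError(QwireError):
    """Invalid argument to a public operation (unknown format, bad name...)."""


class ConfigurationError(QwireError):
    """A config (subunit map, pathway, milestone set) is inconsistent with the model."""


class SelectionError(QwireError):
    """An atom/residue specification did not resolve to the expected atoms."""


class IdentityError(SelectionError):
    """Residue found at the requested position but its residue name mismatched."""


class MissingAtomError(SelectionError):
    """Residue resolved but a requested atom name is absent."""


class DimensionError(QwireError):
    """Vector/grid shapes do not agree."""


class StateError(QwireError):
    """Operation called on an object in an invalid state (e.g. empty kernel list)."""


class GenerationError(QwireError):
    """A synthetic fixture spec is unrealisable or failed its own verification."""


class StabilityError(QwireError):
    """Numerical integration diverged; reduce the time step."""
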