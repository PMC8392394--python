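"""Exception hierarchy shared across the package.

Every error a pipeline stage can raise derives from :class:`MirHairpinError`
so callers (and the CLI) can catch one base class and report a category.
"""


class MirHairpinError(Exception):
    """Base class for all package errors."""

    category = "error"


class FormatError(MirHairpinError):
    """Malformed input file (FASTA, dot-bracket, TSV)."""

    category = "format"


class StructureError(MirHairpinError):
    """Invalid secondary structure (unbalanced brackets, length mismatch)."""

    category = "structure"


class TooShortError(MirHairpinError):
    """Sequence shorter than the minimum an operation supports."""

    category = "too-short"


class TrainingError(MirHairpinError):
    """Invalid training inputs (empty class, degenerate data)."""

    category = "training"


class ConfigurationError(MirHairpinError):
    """Missing or inconsistent configuration (untrained tables, manifest mismatch)."""

    category = "configuration"


class EngineUnavailableError(MirHairpinError):
    """Requested folding engine cannot be used in this environment."""

    category = "engine"
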