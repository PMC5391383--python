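"""Exception hierarchy shared across the package."""


class TailscopeError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(TailscopeError):
    """A coordinate file could not be parsed as PDB."""


class ModelNotFoundError(TailscopeError):
    """The requested MODEL index is absent from a multi-model file."""


class CongruenceError(TailscopeError):
    """Models of a multi-model trajectory file disagree in atom content."""


class SelectionError(TailscopeError):
    """A chain/residue/atom selection matched nothing or is out of range."""


class PTMPatternError(TailscopeError):
    """A PTM pattern targets a residue of an incompatible type."""


class AssignmentError(TailscopeError):
    """Secondary structure cannot be assigned (missing backbone atoms)."""


class StageError(TailscopeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
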