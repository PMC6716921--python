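"""Exception hierarchy shared across the package."""


class AmpMinerError(Exception):
    """Base class for all ampminer errors."""


class FastaFormatError(AmpMinerError):
    """Malformed FASTA input (bad header, empty record, ...)."""


class AlphabetError(AmpMinerError):
    """Sequence contains characters outside the declared alphabet."""


class DegenerateInputError(AmpMinerError):
    """Input too short or otherwise degenerate for the operation."""


class CoordinateError(AmpMinerError):
    """Invalid genomic coordinates (start > end, out of range, ...)."""


class UndefinedMassError(AmpMinerError):
    """Molecular weight requested for a residue with no defined mass."""


class UndefinedPIError(AmpMinerError):
    """Isoelectric point requested for a peptide with no ionizable group."""


class LayoutError(AmpMinerError):
    """Planted features overlap or fall outside their scaffold."""


class ParameterError(AmpMinerError):
    """Parameter outside its valid range."""


class PipelineError(AmpMinerError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
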