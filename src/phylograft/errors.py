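"""Exception hierarchy.

User-facing errors (bad input files, unresolvable labels, contract
violations) derive from :class:`PhylograftError` so the CLI can map them to
exit code 1; anything else is treated as an internal error (exit code 2).
"""


class PhylograftError(Exception):
    """Base class for all user-facing errors raised by phylograft."""


class NewickParseError(PhylograftError):
    """Malformed Newick input; carries the character position of the offending token."""

    def __init__(self, message: str, pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


class TreeError(PhylograftError):
    """Invalid tree operation (unknown leaf, missing branch length, degenerate tree)."""


class SpeciesResolutionError(PhylograftError):
    """A leaf label could not be mapped to a species code."""


class ContractError(PhylograftError):
    """An operation was called outside its precondition (e.g. multiplicity on a paralog)."""


class IngestError(PhylograftError):
    """Annotation/FASTA/ID-map ingestion failure."""


class HitTableError(PhylograftError):
    """Profile-search hit table could not be parsed."""


class PipelineError(PhylograftError):
    """A pipeline stage failed; message names the stage and context."""
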