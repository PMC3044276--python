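"""Exception hierarchy shared by all blastbin modules.

The CLI maps these onto its exit-code contract: usage problems exit 1,
data/format/structure problems exit 2.
"""


class BlastbinError(Exception):
    """Base class for all blastbin errors."""


class StructuralError(BlastbinError):
    """A hierarchy violates its invariants (cycle, multiple roots, orphan)."""


class FormatError(BlastbinError):
    """An input file does not conform to its declared format."""


class UnknownNodeError(BlastbinError, KeyError):
    """A node/pathway/sample identifier was looked up but does not exist."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return BlastbinError.__str__(self)


class DegenerateInputError(BlastbinError):
    """Input is structurally valid but degenerate for the requested operation
    (e.g. a zero-total sample passed to relative normalization)."""
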