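"""Exception hierarchy.

All package errors derive from :class:`SrpAsrError` so callers can catch one
base class; the subclasses mirror the distinct failure modes of the pipeline
stages (parsing, pairing alignment with tree, pruning, domain violations).
"""


class SrpAsrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SrpAsrError):
    """A file or string does not conform to the expected text format."""


class AlignmentError(SrpAsrError):
    """Sequences that must share a coordinate system do not."""


class LabelError(SrpAsrError):
    """A sequence header does not follow the gene_domain_phylum_Accession convention."""


class TreeError(SrpAsrError):
    """A Newick tree is structurally invalid (duplicate leaves, cycles...)."""


class PairingError(SrpAsrError):
    """Tree leaf names and alignment headers do not match."""


class PruneError(SrpAsrError):
    """Pruning removed all descendants on one side of a named node of interest."""


class DomainError(SrpAsrError):
    """An argument is outside the operation's domain (negative branch length...)."""
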