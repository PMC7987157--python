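"""Sequence and alignment I/O.

The master coordinate system for the whole pipeline is the column index of a
gapped FASTA alignment.  Every downstream object (reconstruction profiles,
called ancestral sequences, consensus sequences, trimmed alignments, domain
annotations) is indexed on these columns, so the :class:`Alignment` container
validates rectangularity and alphabet on construction and is never realigned.

Sequence headers follow the convention ``gene_domain_phylum_Accession`` used
throughout the supplementary-file dialects; :func:`parse_label` round-trips
them into :class:`TaxonLabel`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, FormatError, LabelError

#: Canonical one-letter residue ordering shared with the rate-model tables.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
GAP = "-"
UNKNOWN = "X"
#: Integer code used for gap/unknown cells in encoded alignments (missing data).
MISSING_CODE = 20

VALID_CHARS = frozenset(AA_ORDER) | {GAP, UNKNOWN}

KNOWN_GENES = ("FtsY", "Ffh", "FlhA", "SS", "SecY")


@dataclass(frozen=True)
class TaxonLabel:
    """Parsed ``gene_domain_phylum_Accession`` header."""

    gene: str
    domain: str
    taxon_group: str
    accession: str

    def format(self) -> str:
        return "_".join((self.gene, self.domain, self.taxon_group, self.accession))


def parse_label(header: str) -> TaxonLabel:
    """Split an underscore-joined header into its four semantic fields.

    The gene is the first token and the accession the last; any middle tokens
    beyond the taxonomic domain are folded into ``taxon_group`` because
    superphylum names may themselves contain underscores.
    """
    tokens = header.split("_")
    if len(tokens) < 4:
        raise LabelError(f"header {header!r} has fewer than 4 underscore-separated tokens")
    gene = tokens[0]
    if gene not in KNOWN_GENES:
        raise LabelError(f"header {header!r}: unknown gene token {gene!r} (expected one of {KNOWN_GENES})")
    return TaxonLabel(gene=gene, domain=tokens[1], taxon_group="_".join(tokens[2:-1]), accession=tokens[-1])


class Alignment:
    """Rectangular gapped amino-acid alignment.

    Parameters
    ----------
    records:
        Iterable of ``(header, sequence)`` pairs.  Sequences are uppercased
        and ``.`` is normalised to ``-`` on construction.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        cleaned: list[tuple[str, str]] = []
        n_columns = None
        for header, seq in records:
            seq = seq.upper().replace(".", GAP)
            if n_columns is None:
                n_columns = len(seq)
                if n_columns == 0:
                    raise FormatError(f"record {header!r} has length 0")
            elif len(seq) != n_columns:
                raise AlignmentError(
                    f"record {header!r} has length {len(seq)}, expected {n_columns}: ragged alignment"
                )
            for col, ch in enumerate(seq):
                if ch not in VALID_CHARS:
                    raise FormatError(f"record {header!r}, column {col}: illegal symbol {ch!r}")
            cleaned.append((header, seq))
        if not cleaned:
            raise FormatError("alignment contains no records")
        self._records = cleaned
        self.n_columns: int = n_columns  # type: ignore[assignment]
        self._index = {h: i for i, (h, _) in enumerate(cleaned)}
        if len(self._index) != len(cleaned):
            seen = set()
            dup = next(h for h, _ in cleaned if h in seen or seen.add(h))
            raise AlignmentError(f"duplicate record header {dup!r}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, header: str) -> str:
        return self._records[self._index[header]][1]

    def __contains__(self, header: str) -> bool:
        return header in self._index

    @property
    def headers(self) -> list[str]:
        return [h for h, _ in self._records]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self._records]

    def subset(self, headers: Sequence[str]) -> "Alignment":
        """Row subset preserving master columns; order follows ``headers``."""
        missing = [h for h in headers if h not in self._index]
        if missing:
            raise AlignmentError(f"headers not in alignment: {missing[:5]}")
        return Alignment((h, self[h]) for h in headers)

    def encoded(self) -> np.ndarray:
        """(n_records, n_columns) int8 matrix; gap and X map to MISSING_CODE."""
        out = np.empty((len(self), self.n_columns), dtype=np.int8)
        for i, (_, seq) in enumerate(self._records):
            out[i] = [AA_INDEX.get(c, MISSING_CODE) for c in seq]
        return out

    def labels(self) -> list[TaxonLabel]:
        return [parse_label(h) for h in self.headers]


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; all records must share one length."""
    records = [(rec.id if rec.description == rec.id else rec.description, str(rec.seq))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Alignment(records)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fasta_alignment(path: str | Path, alignment: Alignment, width: int = 60) -> None:
    write_fasta(path, alignment, width=width)


def ungapped_length(seq: str) -> int:
    """Number of non-gap characters (X counts: it is an unknown residue, not a gap)."""
    return len(seq) - seq.count(GAP)


@dataclass
class ReconstructionSet:
    """Replicate ancestral reconstructions at one node and gap threshold.

    All member sequences live on the master columns so they are directly
    comparable for consensus building.
    """

    node_id: str
    gap_threshold: int
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= self.gap_threshold <= 99:
            raise FormatError(f"gap_threshold {self.gap_threshold} outside [1, 99]")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError("replicate sequences differ in column count")

    @property
    def n_members(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def read_newick(path: str | Path):
    """Parse a Newick tree file (delegates to :mod:`srpasr.tree`)."""
    from .tree import PhyloTree

    return PhyloTree.from_newick_file(path)
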