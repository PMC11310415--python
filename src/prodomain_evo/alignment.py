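"""Ortholog alignment I/O, reference coordinates, and modal consensus.

The conservation analysis in this package is anchored on a multi-FASTA
amino-acid alignment of pro-IL-1alpha orthologs.  This module reads and
writes such alignments, maps 1-based residue positions of an ungapped
reference sequence (conventionally the human ortholog) onto 0-based
alignment columns, computes the per-column modal consensus (the most
frequent symbol, gaps included), and removes columns where the gap is the
modal symbol.

Header convention
-----------------
FASTA headers of the form ``species|accession|isoform`` are parsed into
metadata fields; species names may use underscores in place of spaces.
Headers that do not follow the convention are kept whole as the species
field.  The full header string is the row's unique ``sequence_id``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: symbols accepted in alignment rows: the 20 amino acids, ambiguity X, gap
ALPHABET = frozenset(AA20 | {"X", GAP})


class AlignmentShapeError(ValueError):
    """Rows of unequal length, or an empty alignment."""


@dataclass(frozen=True)
class AlignmentRow:
    """One aligned sequence with its parsed metadata."""

    sequence_id: str
    species: str
    accession: str
    isoform: str
    residues: str

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class DomainSpec:
    """A named interval on the 1-based reference residue coordinate system."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"domain {self.name!r}: need 1 <= start <= end, got {self.start}-{self.end}"
            )

    @property
    def residues(self) -> range:
        """1-based residue indices covered by the domain (inclusive)."""
        return range(self.start, self.end + 1)


#: Pro-domain landmarks on the human reference: two HAT-binding domains,
#: the nuclear localisation sequence with its KKRR core, and the whole
#: pro-domain (Met1 to Arg112).
HAT1 = DomainSpec("HAT1", 7, 19)
NLS = DomainSpec("NLS", 78, 90)
HAT2 = DomainSpec("HAT2", 98, 108)
KKRR = DomainSpec("KKRR", 82, 85)
PRO_DOMAIN = DomainSpec("PRO", 1, 112)
DEFAULT_DOMAINS = (HAT1, NLS, HAT2, PRO_DOMAIN)


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) >= 2:
        species = parts[0].replace("_", " ").strip()
        accession = parts[1].strip()
        isoform = parts[2].strip() if len(parts) >= 3 else ""
        return species, accession, isoform
    return header.strip(), "", ""


@dataclass
class OrthologAlignment:
    """Equal-length aligned amino-acid rows with per-row metadata."""

    rows: list[AlignmentRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentShapeError("alignment has no rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"rows have unequal lengths: {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise AlignmentShapeError("alignment has zero columns")
        ids = [r.sequence_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate sequence ids: {dupes}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0].residues)

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.rows})

    def column(self, j: int) -> str:
        """Symbols of 0-based column *j*, top to bottom."""
        return "".join(r.residues[j] for r in self.rows)

    def get(self, sequence_id: str) -> AlignmentRow:
        for r in self.rows:
            if r.sequence_id == sequence_id:
                return r
        raise KeyError(f"sequence id not found: {sequence_id!r}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def read_alignment(path: str | Path) -> OrthologAlignment:
    """Read a multi-FASTA alignment; gap character ``-``.

    Raises :class:`AlignmentShapeError` for unequal row lengths and
    ``ValueError`` for an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rows = []
    for rec in records:
        species, accession, isoform = _parse_header(rec.description)
        rows.append(
            AlignmentRow(
                sequence_id=rec.description,
                species=species,
                accession=accession,
                isoform=isoform,
                residues=str(rec.seq).upper(),
            )
        )
    return OrthologAlignment(rows)


def write_alignment(aln: OrthologAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.residues), id=r.sequence_id.split()[0], description="")
        for r in aln.rows
    ]
    # keep the full header if it contains spaces
    for rec, row in zip(records, aln.rows):
        if rec.id != row.sequence_id:
            rec.description = row.sequence_id[len(rec.id) :].strip()
    SeqIO.write(records, str(path), "fasta")


@dataclass
class ReferenceMap:
    """Bidirectional map between 1-based reference residues and 0-based columns."""

    reference_id: str
    residue_to_column: dict[int, int]
    column_to_residue: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.column_to_residue:
            self.column_to_residue = {c: r for r, c in self.residue_to_column.items()}

    def columns_for(self, domain: DomainSpec) -> list[int]:
        """Alignment columns of a reference-coordinate domain, ascending.

        Every residue of the domain must be present in the map.
        """
        missing = [i for i in domain.residues if i not in self.residue_to_column]
        if missing:
            raise KeyError(
                f"domain {domain.name!r}: reference residues {missing} absent from map"
            )
        return [self.residue_to_column[i] for i in domain.residues]


def build_reference_map(aln: OrthologAlignment, reference_id: str) -> ReferenceMap:
    """Anchor the reference coordinate system on one alignment row.

    Residue ``i`` (1-based) maps to the column holding the i-th non-gap
    symbol of the reference row.
    """
    ref = aln.get(reference_id)
    mapping: dict[int, int] = {}
    residue = 0
    for col, sym in enumerate(ref.residues):
        if sym != GAP:
            residue += 1
            mapping[residue] = col
    return ReferenceMap(reference_id=reference_id, residue_to_column=mapping)


@dataclass(frozen=True)
class ColumnMode:
    symbol: str
    count: int

    @property
    def gap_is_modal(self) -> bool:
        return self.symbol == GAP


@dataclass
class ModalConsensus:
    """Per-column modal symbol of an alignment, gaps counted as a symbol."""

    columns: list[ColumnMode]

    @property
    def modal_string(self) -> str:
        return "".join(c.symbol for c in self.columns)

    def __len__(self) -> int:
        return len(self.columns)


def modal_consensus(aln: OrthologAlignment) -> ModalConsensus:
    """Most frequent symbol per column, counting gaps.

    Tie-break: any non-gap symbol is preferred over the gap; among non-gap
    symbols the lexicographically smallest one-letter code wins.  This keeps
    tied columns in the alignment rather than discarding them as gap-modal.
    """
    cols = []
    for j in range(aln.column_count):
        counts = Counter(aln.column(j))
        top = max(counts.values())
        winner = min((s for s, c in counts.items() if c == top), key=lambda s: (s == GAP, s))
        cols.append(ColumnMode(symbol=winner, count=top))
    return ModalConsensus(columns=cols)


def drop_gap_modal_columns(
    aln: OrthologAlignment, consensus: ModalConsensus
) -> tuple[OrthologAlignment | None, list[int]]:
    """Remove columns whose modal symbol is the gap.

    Returns the filtered alignment (``None`` if every column was gap-modal)
    and the list of retained original 0-based column indices, enabling
    coordinate back-mapping.
    """
    if len(consensus) != aln.column_count:
        raise AlignmentShapeError("consensus length does not match alignment width")
    retained = [j for j, col in enumerate(consensus.columns) if not col.gap_is_modal]
    if not retained:
        return None, []
    rows = [
        AlignmentRow(
            sequence_id=r.sequence_id,
            species=r.species,
            accession=r.accession,
            isoform=r.isoform,
            residues="".join(r.residues[j] for j in retained),
        )
        for r in aln.rows
    ]
    return OrthologAlignment(rows), retained


def parse_domains(specs: Iterable[str]) -> list[DomainSpec]:
    """Parse ``name:start-end`` triples (1-based inclusive) into DomainSpecs."""
    out = []
    for s in specs:
        name, _, span = s.partition(":")
        start, _, end = span.partition("-")
        if not (name and start and end):
            raise ValueError(f"malformed domain spec {s!r}; expected name:start-end")
        out.append(DomainSpec(name, int(start), int(end)))
    return out
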