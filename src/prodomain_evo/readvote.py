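"""Sequencing-read base votes over an exon query.

Re-implements the sequence-read analysis used to date motif-loss events:
nucleotide reads are locally aligned to an exon query sequence on both
strands, hits are filtered by alignment score (strictly greater than a
cut-off, default 80) and capped at the top 100, and for every query
position coding for the KKRR motif the percentage of read bases matching
the human reference base is tallied.  The per-position majority base is
translated into the consensus amino-acid motif.

Scoring is an affine-gap Smith-Waterman with blastn-like defaults
(match +2, mismatch -3, gap open 5, gap extend 2; a gap of length k costs
open + extend*k).  Scores are in this scheme, not BLAST raw scores; the
cut-off is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .motif import translate_nt

#: reference nucleotides coding for the human KKRR motif
KKRR_CODONS = "aagaagagacgg"


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scores; gap of length k costs ``gap_open + gap_extend*k``."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2


@dataclass
class AlignmentHit:
    """Best local alignment of one read against the query, either strand."""

    read_id: str
    score: float
    strand: str  # '+' or '-'
    query_interval: tuple[int, int]  # 0-based half-open on the query
    base_calls: dict[int, str]  # query position -> read base or '-' (deletion)


def read_reads(path: str | Path) -> list[ReadRecord]:
    """Read FASTA or FASTQ (auto-detected; qualities ignored)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    records = [
        ReadRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)
    ]
    if not records:
        raise ValueError(f"no reads in {path}")
    ids = [r.read_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids")
    return records


def read_query(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single-record FASTA query, got {len(records)}")
    return str(records[0].seq).upper()


def _aligner(scoring: Scoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # PairwiseAligner charges open on the first gap position, so a gap of
    # length k costs -(open_gap_score) - (k-1)*(-extend) = open+extend*k here.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _base_calls(alignment) -> tuple[tuple[int, int], dict[int, str]]:
    """Query-projected base calls from one pairwise alignment.

    Query (target) positions aligned to a read base get that base; query
    positions spanned by the local alignment but deleted in the read get
    '-'.  Read insertions do not map to query positions and are dropped.
    """
    t_blocks, q_blocks = alignment.aligned
    read_seq = str(alignment.query)
    calls: dict[int, str] = {}
    for (t0, t1), (r0, r1) in zip(t_blocks, q_blocks):
        for off in range(t1 - t0):
            calls[t0 + off] = read_seq[r0 + off]
    start = int(t_blocks[0][0])
    end = int(t_blocks[-1][1])
    for pos in range(start, end):
        calls.setdefault(pos, "-")
    return (start, end), calls


def local_align(
    read: ReadRecord, query: str, scoring: Scoring = Scoring()
) -> AlignmentHit:
    """Best affine-gap Smith-Waterman hit of a read on either strand.

    The reverse complement is also aligned and the better orientation kept
    (ties go to the forward strand).  Base calls are reported in query
    coordinates.
    """
    if not read.sequence or not query:
        raise ValueError("empty read or query")
    aligner = _aligner(scoring)
    fwd = read.sequence
    rev = reverse_complement(fwd)
    score_f = aligner.score(query, fwd)
    score_r = aligner.score(query, rev)
    strand, seq, score = ("+", fwd, score_f) if score_f >= score_r else ("-", rev, score_r)
    alignment = aligner.align(query, seq)[0]
    interval, calls = _base_calls(alignment)
    return AlignmentHit(
        read_id=read.read_id,
        score=float(score),
        strand=strand,
        query_interval=interval,
        base_calls=calls,
    )


def filter_hits(
    hits: list[AlignmentHit], min_score: float = 80, cap: int = 100
) -> list[AlignmentHit]:
    """Keep hits scoring strictly above ``min_score``; sort by score
    descending (ties: read id ascending); truncate to the top ``cap``."""
    if min_score < 0 or cap < 1:
        raise ValueError("min_score must be >= 0 and cap >= 1")
    kept = [h for h in hits if h.score > min_score]
    kept.sort(key=lambda h: (-h.score, h.read_id))
    return kept[:cap]


@dataclass
class VoteTable:
    """Per-position base tallies over the motif interval of the query."""

    table: pd.DataFrame  # index: 0-based query position
    motif_interval: tuple[int, int]
    reference_motif: str

    def percent_match(self, position: int) -> float:
        """Percent of covering bases matching the reference at a 0-based
        query position (NaN when uncovered)."""
        return float(self.table.loc[position, "percent_match"])


def vote(
    hits: list[AlignmentHit],
    motif_interval: tuple[int, int],
    reference_motif: str,
    query_length: int | None = None,
) -> VoteTable:
    """Tally covering read bases per motif position against the reference.

    ``motif_interval`` is 0-based half-open on the query; N bases count in
    coverage but never as reference-matching.  Positions with zero
    coverage have undefined (NaN) percent match.
    """
    start, end = motif_interval
    if start < 0 or end <= start:
        raise ValueError(f"bad motif interval {motif_interval}")
    if query_length is not None and end > query_length:
        raise ValueError("motif interval outside query")
    if len(reference_motif) != end - start:
        raise ValueError("reference motif length does not match interval")
    ref = reference_motif.upper()
    symbols = ["A", "C", "G", "T", "N", "-"]
    rows = []
    for i, pos in enumerate(range(start, end)):
        counts = dict.fromkeys(symbols, 0)
        for h in hits:
            base = h.base_calls.get(pos)
            if base is not None:
                counts[base if base in counts else "N"] += 1
        coverage = sum(counts.values())
        ref_base = ref[i]
        pct = 100.0 * counts[ref_base] / coverage if coverage else math.nan
        rows.append(
            {
                "position": pos,
                "ref_base": ref_base,
                **{f"count_{s}" if s != "-" else "count_gap": counts[s] for s in symbols},
                "coverage": coverage,
                "percent_match": pct,
            }
        )
    table = pd.DataFrame(rows).set_index("position")
    return VoteTable(table=table, motif_interval=motif_interval, reference_motif=ref)


@dataclass(frozen=True)
class ConsensusCall:
    nucleotides: str
    amino_acids: str
    tie_positions: tuple[int, ...] = ()  # 0-based query positions resolved to reference
    uncovered_positions: tuple[int, ...] = ()


def consensus_motif(vote_table: VoteTable) -> ConsensusCall:
    """Majority base per motif position, translated to amino acids.

    Ties go to the reference base and are flagged; uncovered positions are
    called N and translate into X.
    """
    nts = []
    ties = []
    uncovered = []
    for pos, row in vote_table.table.iterrows():
        counts = {b: int(row[f"count_{b}"]) for b in "ACGT"}
        if row["coverage"] == 0 or max(counts.values()) == 0:
            uncovered.append(int(pos))
            nts.append("N")
            continue
        top = max(counts.values())
        winners = [b for b, c in counts.items() if c == top]
        if len(winners) == 1:
            nts.append(winners[0])
        else:
            ties.append(int(pos))
            nts.append(str(row["ref_base"]))
    nt = "".join(nts)
    # translate whole codons only; a trailing partial codon is dropped
    return ConsensusCall(
        nucleotides=nt.lower(),
        amino_acids=translate_nt(nt[: len(nt) // 3 * 3]),
        tie_positions=tuple(ties),
        uncovered_positions=tuple(uncovered),
    )
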