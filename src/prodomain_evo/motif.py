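"""KKRR motif extraction, NLS-status classification, and a propensity score.

The functional core of the pro-IL-1alpha nuclear localisation sequence is
the basic tetrapeptide KKRR (reference residues 82-85, inside the NLS span
78-90, GKVLKKRRLSLSQ).  A sequence keeps NLS function when the motif is
intact; substitutions to another basic residue (K or R) retain basic
character and are classed *conservative*; any other substitution or a gap
is a predicted *loss*; an ambiguous residue (X) makes the call *unknown*.

``nls_propensity`` is a deliberately simple basic-residue density score
over sliding windows (it is NOT the NLS-mapper algorithm): it is used only
for the direction of predictions, e.g. that replacing KKRR by KNRW lowers
the score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .alignment import AA20, GAP, KKRR, AlignmentRow, DomainSpec, ReferenceMap

MOTIF_REFERENCE = "KKRR"
BASIC = frozenset("KR")


class MotifClass(str, enum.Enum):
    INTACT = "intact"
    CONSERVATIVE = "conservative"
    LOSS = "loss"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MotifCall:
    """Classified motif of one sequence."""

    sequence_id: str
    species: str
    motif: str
    motif_class: MotifClass
    substituted_positions: tuple[tuple[int, str], ...] = ()  # (1-based pos, residue)


def extract_motif(
    row: AlignmentRow, refmap: ReferenceMap, kkrr_domain: DomainSpec = KKRR
) -> str:
    """Symbols at the alignment columns of the motif's reference residues.

    Gaps are preserved; a reference residue absent from the map raises
    ``KeyError``.
    """
    cols = refmap.columns_for(kkrr_domain)
    return "".join(row.residues[j] for j in cols)


def classify_motif(motif: str, reference: str = MOTIF_REFERENCE) -> MotifClass:
    """Classify a motif string against the basic-residue reference.

    Total and deterministic over the 21-symbol alphabet (+ gap):
    ``X`` anywhere -> unknown; identical to the reference -> intact;
    all substitutions to K/R and no gap -> conservative; otherwise loss.
    """
    if len(motif) != len(reference):
        raise ValueError(f"motif length {len(motif)} != reference length {len(reference)}")
    motif = motif.upper()
    if "X" in motif:
        return MotifClass.UNKNOWN
    if motif == reference:
        return MotifClass.INTACT
    subs = [(i, m) for i, (m, r) in enumerate(zip(motif, reference)) if m != r]
    if all(m in BASIC for _, m in subs):
        return MotifClass.CONSERVATIVE
    return MotifClass.LOSS


def call_motif(
    row: AlignmentRow, refmap: ReferenceMap, kkrr_domain: DomainSpec = KKRR
) -> MotifCall:
    """Extract and classify the motif of one aligned row."""
    motif = extract_motif(row, refmap, kkrr_domain)
    subs = tuple(
        (i + 1, m) for i, (m, r) in enumerate(zip(motif, MOTIF_REFERENCE)) if m != r
    )
    return MotifCall(
        sequence_id=row.sequence_id,
        species=row.species,
        motif=motif,
        motif_class=classify_motif(motif),
        substituted_positions=subs,
    )


STATUS_MIXED = "mixed"


def call_species_status(calls: list[MotifCall]) -> dict[str, str]:
    """Collapse per-isoform calls to a per-species status.

    A species is assigned a definite class only when every isoform agrees;
    disagreeing isoforms are flagged ``mixed`` for manual review (in
    particular, a species is called *loss* only if ALL its isoforms are).
    """
    by_species: dict[str, set[MotifClass]] = {}
    for c in calls:
        by_species.setdefault(c.species, set()).add(c.motif_class)
    out = {}
    for sp, classes in sorted(by_species.items()):
        out[sp] = next(iter(classes)).value if len(classes) == 1 else STATUS_MIXED
    return out


@dataclass(frozen=True)
class NlsPropensityScore:
    """Best sliding-window basic-residue density of a sequence."""

    sequence_id: str
    best_window: tuple[int, int]  # 1-based inclusive, on the ungapped sequence
    score: float
    contains_motif_region: bool = False


def nls_propensity(
    sequence: str,
    window_lengths: range = range(8, 14),
    *,
    sequence_id: str = "",
    motif_region: tuple[int, int] | None = None,
) -> NlsPropensityScore:
    """Maximum basic-residue density over sliding windows.

    Score of a window = (#K + #R)/window length; the maximum over all
    windows of lengths 8-13 is reported together with the best window
    (ties: smallest start, then shortest window).  ``motif_region`` is a
    1-based inclusive interval on the same coordinates; the result records
    whether the best window overlaps it.  The score is translation
    invariant and additive per residue, so replacing a basic residue in
    the (unique) best window by a non-basic one strictly lowers it.
    """
    seq = sequence.upper().replace(GAP, "")
    if not seq:
        raise ValueError("empty sequence")
    basic = [1 if a in BASIC else 0 for a in seq]
    prefix = [0]
    for b in basic:
        prefix.append(prefix[-1] + b)

    best_score = -1.0
    best = (1, min(len(seq), window_lengths[0] if window_lengths else 1))
    for start in range(len(seq)):
        for w in window_lengths:
            end = start + w
            if end > len(seq):
                break
            score = (prefix[end] - prefix[start]) / w
            if score > best_score + 1e-12:
                best_score = score
                best = (start + 1, end)
    if best_score < 0:  # sequence shorter than every window length
        w = len(seq)
        best_score = sum(basic) / w
        best = (1, w)
    contains = False
    if motif_region is not None:
        contains = best[0] <= motif_region[1] and best[1] >= motif_region[0]
    return NlsPropensityScore(
        sequence_id=sequence_id,
        best_window=best,
        score=best_score,
        contains_motif_region=contains,
    )


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Uncertain codons (containing N) translate to X.  The printed motif
    codons behave as expected: aagaagagacgg -> KKRR, aagaagagatgg -> KKRW,
    aagaacagatgg -> KNRW.
    """
    if len(nt) % 3:
        raise ValueError(f"nucleotide length {len(nt)} is not a multiple of 3")
    return str(Seq(nt.upper()).translate())
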