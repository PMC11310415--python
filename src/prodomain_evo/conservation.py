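"""Per-sequence, per-domain conservation relative to the modal consensus.

A sequence's conservation over a domain is the fraction of domain columns
(after gap-modal column removal) whose residue equals the modal amino acid
of that column.  Gaps and ambiguity codes in the scored row never match;
a column whose modal symbol is not one of the 20 amino acids never scores.
Summaries are reported separately for sequences with an intact versus a
mutated NLS core motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import (
    AA20,
    AlignmentRow,
    AlignmentShapeError,
    DomainSpec,
    ModalConsensus,
    ReferenceMap,
)
from .motif import MotifCall, MotifClass

GROUP_INTACT = "intact_NLS"
GROUP_MUTANT = "mutant_NLS"
GROUP_OTHER = "other"


def match_profile(
    row: AlignmentRow, consensus: ModalConsensus, retained_columns: list[int]
) -> np.ndarray:
    """Binary match vector over retained columns.

    Entry k is 1 iff the modal symbol of retained column k is an amino acid
    and the row carries exactly that amino acid there.
    """
    width = len(consensus)
    if len(row.residues) != width:
        raise AlignmentShapeError(
            f"row {row.sequence_id!r} has {len(row.residues)} columns, consensus {width}"
        )
    out = np.zeros(len(retained_columns), dtype=np.int8)
    for k, j in enumerate(retained_columns):
        modal = consensus.columns[j].symbol
        out[k] = 1 if modal in AA20 and row.residues[j] == modal else 0
    return out


@dataclass(frozen=True)
class DomainConservation:
    """Conservation of one sequence over one domain."""

    domain: str
    matched: int
    total: int  # domain columns surviving gap-modal removal
    total_prefilter: int  # domain columns before removal

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def fraction(self) -> float:
        """matched/total; NaN when the domain was entirely removed."""
        return self.matched / self.total if self.total else float("nan")


def domain_conservation(
    profile: np.ndarray,
    domain: DomainSpec,
    refmap: ReferenceMap,
    retained_columns: list[int],
) -> DomainConservation:
    """Fraction of a domain's surviving columns matching the modal residue.

    The denominator is the number of domain columns that survived gap-modal
    removal; a domain with no surviving columns is flagged undefined rather
    than silently scored 0.
    """
    domain_cols = set(refmap.columns_for(domain))
    col_to_k = {j: k for k, j in enumerate(retained_columns)}
    ks = [col_to_k[j] for j in domain_cols if j in col_to_k]
    matched = int(profile[ks].sum()) if ks else 0
    return DomainConservation(
        domain=domain.name,
        matched=matched,
        total=len(ks),
        total_prefilter=len(domain_cols),
    )


def _group_of(call: MotifCall, conservative_as_loss: bool = False) -> str:
    if call.motif_class is MotifClass.INTACT:
        return GROUP_INTACT
    if call.motif_class is MotifClass.CONSERVATIVE:
        return GROUP_MUTANT if conservative_as_loss else GROUP_INTACT
    if call.motif_class is MotifClass.LOSS:
        return GROUP_MUTANT
    return GROUP_OTHER


def group_summary(
    profiles: dict[str, np.ndarray],
    motif_calls: dict[str, MotifCall],
    domains: list[DomainSpec],
    refmap: ReferenceMap,
    retained_columns: list[int],
    *,
    rows: dict[str, AlignmentRow] | None = None,
    conservative_as_loss: bool = False,
    collapse_species: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence and per-group conservation tables.

    Parameters
    ----------
    profiles, motif_calls
        Keyed by sequence id; every profile must have a motif call.
    rows
        Optional metadata source (species names; and, with
        ``collapse_species``, the longest isoform per species is kept).
    conservative_as_loss
        Group substitutions-to-K/R with the losses instead of with intact.
    collapse_species
        Keep a single sequence per species (longest ungapped isoform,
        ties broken by sequence id) instead of all isoforms.

    Returns ``(per_sequence, summary)``: per_sequence has one row per
    (sequence, domain); summary has mean/median/IQR/n per (group, domain).
    Empty groups are simply absent from the summary.
    """
    missing = sorted(set(profiles) - set(motif_calls))
    if missing:
        raise KeyError(f"profiles without motif calls: {missing}")

    ids = sorted(profiles)
    if collapse_species and rows:
        best: dict[str, str] = {}
        for sid in ids:
            sp = rows[sid].species
            if sp not in best or (
                len(rows[sid].ungapped()),
                sid,
            ) > (len(rows[best[sp]].ungapped()), best[sp]):
                # longer isoform wins; deterministic tie-break on id
                if sp in best and len(rows[sid].ungapped()) == len(rows[best[sp]].ungapped()):
                    best[sp] = min(sid, best[sp])
                else:
                    best[sp] = sid
        ids = sorted(best.values())

    records = []
    for sid in ids:
        call = motif_calls[sid]
        group = _group_of(call, conservative_as_loss)
        species = rows[sid].species if rows else call.species
        for dom in domains:
            dc = domain_conservation(profiles[sid], dom, refmap, retained_columns)
            records.append(
                {
                    "sequence_id": sid,
                    "species": species,
                    "group": group,
                    "domain": dom.name,
                    "matched": dc.matched,
                    "total": dc.total,
                    "total_prefilter": dc.total_prefilter,
                    "fraction": dc.fraction,
                }
            )
    per_sequence = pd.DataFrame.from_records(records)

    defined = per_sequence[per_sequence["total"] > 0]
    summary = (
        defined.groupby(["group", "domain"])["fraction"]
        .agg(
            mean="mean",
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n="count",
        )
        .reset_index()
    )
    summary["iqr"] = summary["q75"] - summary["q25"]
    return per_sequence, summary


def barcode_table(
    profiles: dict[str, np.ndarray],
    consensus: ModalConsensus,
    retained_columns: list[int],
) -> pd.DataFrame:
    """Per-column match track (one row per sequence, one column per retained
    position) for plotting solid-colour/white-gap conservation barcodes."""
    data = {sid: profiles[sid] for sid in sorted(profiles)}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.columns = pd.Index(retained_columns, name="alignment_column")
    df.index.name = "sequence_id"
    return df
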