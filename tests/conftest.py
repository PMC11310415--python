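"""Shared fixtures: tiny hand-built alignments and simulated inputs."""

from __future__ import annotations

import numpy as np
import pytest

from prodomain_evo.alignment import (
    AlignmentRow,
    OrthologAlignment,
    build_reference_map,
    drop_gap_modal_columns,
    modal_consensus,
)


def make_alignment(seqs: dict[str, str]) -> OrthologAlignment:
    """Build an alignment from {header: residues}; headers follow the
    species|accession|isoform convention where they contain '|'."""
    rows = []
    for header, residues in seqs.items():
        parts = header.split("|")
        rows.append(
            AlignmentRow(
                sequence_id=header,
                species=parts[0].replace("_", " ") if len(parts) >= 2 else header,
                accession=parts[1] if len(parts) >= 2 else "",
                isoform=parts[2] if len(parts) >= 3 else "",
                residues=residues,
            )
        )
    return OrthologAlignment(rows)


@pytest.fixture
def toy_alignment() -> OrthologAlignment:
    """Five rows, 10 columns; the human row is gap-free so its residues
    index the columns directly."""
    return make_alignment(
        {
            "human|H1|1": "MKKRRASTWQ",
            "mouse|M1|1": "MKKRRASTWQ",
            "orca|O1|1": "MKNRWASTWQ",
            "beaver|B1|1": "MKKRWAS-WQ",
            "devil|D1|1": "M--RRASTWQ",
        }
    )


@pytest.fixture
def toy_consensus(toy_alignment):
    return modal_consensus(toy_alignment)


@pytest.fixture
def toy_refmap(toy_alignment):
    return build_reference_map(toy_alignment, "human|H1|1")


@pytest.fixture
def toy_retained(toy_alignment, toy_consensus):
    _, retained = drop_gap_modal_columns(toy_alignment, toy_consensus)
    return retained


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
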