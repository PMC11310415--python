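"""Seeded generators for every pipeline stage.

Three generators emulate the statistical structure of the real inputs so
the whole pipeline is testable without downloads:

* ``simulate_family`` — an ortholog family of 112-residue pro-domain
  sequences evolving on a species tree with domain-specific per-site
  substitution probabilities and lineage-specific knockouts of the KKRR
  core motif (e.g. castorimorpha -> KKRW, toothed whales -> KNRW);
* ``simulate_reads`` — nucleotide reads drawn uniformly over an exon
  carrying the motif codons, with planted substitutions, a per-base error
  rate and a strand mix;
* ``simulate_lfq`` — a MaxQuant-dialect LFQ matrix with two groups of
  replicates, spiked target-enriched proteins, intensity-dependent
  (left-censored) missingness and flagged contaminant/reverse rows.

Each generator returns its truth table alongside the data and is fully
deterministic for a given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AA20, HAT1, HAT2, KKRR, NLS, AlignmentRow, OrthologAlignment

_AA = sorted(AA20)

#: human NLS span (reference residues 78-90) planted in the ancestor so
#: that the KKRR core sits at 82-85
NLS_ANCESTRAL = "GKVLKKRRLSLSQ"

#: motif codons of the reference exon (human KKRR)
MOTIF_NT = "aagaagagacgg"

REFERENCE_ID = "Homo_sapiens|REF|1"


# ---------------------------------------------------------------------------
# species trees


@dataclass
class Clade:
    """Nested clade with a branch length in arbitrary time units."""

    name: str
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["Clade"]:
        if self.is_tip:
            return [self]
        return [t for c in self.children for t in c.tips()]

    def find(self, name: str) -> "Clade | None":
        if self.name == name:
            return self
        for c in self.children:
            found = c.find(name)
            if found is not None:
                return found
        return None

    @classmethod
    def from_dict(cls, spec: dict) -> "Clade":
        return cls(
            name=spec["name"],
            length=float(spec.get("length", 0.0)),
            children=[cls.from_dict(c) for c in spec.get("children", [])],
        )


def _ladder(names: list[str], depth: float) -> list[Clade]:
    return [Clade(name=n, length=depth) for n in names]


def fixture_tree() -> Clade:
    """Small built-in species tree mirroring the study's clades.

    Ultrametric with unit root-to-tip depth; contains the rodent suborder
    castorimorpha (with a kangaroo-rat subclade), toothed and baleen
    whales, marsupials and monotremes alongside other placentals.
    """
    return Clade(
        name="mammalia",
        children=[
            Clade(
                name="theria",
                length=0.2,
                children=[
                    Clade(
                        name="placentalia",
                        length=0.3,
                        children=[
                            Clade(
                                name="rodentia",
                                length=0.2,
                                children=[
                                    Clade(
                                        name="castorimorpha",
                                        length=0.1,
                                        children=[
                                            Clade("beaver", 0.2),
                                            Clade(
                                                name="kangaroo_rats",
                                                length=0.1,
                                                children=_ladder(
                                                    ["kangaroo_rat_ordii", "kangaroo_rat_spectabilis"],
                                                    0.1,
                                                ),
                                            ),
                                        ],
                                    ),
                                    Clade(
                                        name="myomorpha",
                                        length=0.1,
                                        children=_ladder(["mouse", "rat"], 0.2),
                                    ),
                                ],
                            ),
                            Clade(
                                name="cetacea",
                                length=0.3,
                                children=[
                                    Clade(
                                        name="odontoceti",
                                        length=0.1,
                                        children=_ladder(["orca", "sperm_whale"], 0.1),
                                    ),
                                    Clade(
                                        name="mysticeti",
                                        length=0.1,
                                        children=_ladder(["blue_whale", "minke_whale"], 0.1),
                                    ),
                                ],
                            ),
                            Clade("human", 0.5),
                        ],
                    ),
                    Clade(
                        name="marsupialia",
                        length=0.4,
                        children=_ladder(["tasmanian_devil", "koala", "brushtail"], 0.4),
                    ),
                ],
            ),
            Clade(
                name="monotremata",
                length=0.6,
                children=_ladder(["platypus", "echidna"], 0.4),
            ),
        ],
    )


def balanced_tree(n_species: int, knockout_clades: int = 2, knockout_size: int = 5) -> Clade:
    """Star tree with ``n_species`` tips on unit-length independent branches.

    The first ``knockout_clades`` clades are named ``clade_0``, ``clade_1``
    ... and hold ``knockout_size`` species each; remaining species sit in a
    background clade.  Clade nodes carry zero-length branches, so they only
    group tips (for knockout targeting) without inducing shared mutations:
    root-to-tip paths are independent and of length 1, which makes the
    expected mismatch fraction against the modal consensus exactly the
    per-site substitution probability — the property parameter-recovery
    simulations rely on.  (``fixture_tree`` keeps realistic shared
    branches instead.)
    """
    if knockout_clades * knockout_size > n_species:
        raise ValueError("knockout clades larger than the species count")
    clades = []
    idx = 0
    for k in range(knockout_clades):
        names = [f"species_{idx + i:03d}" for i in range(knockout_size)]
        idx += knockout_size
        clades.append(Clade(name=f"clade_{k}", length=0.0, children=_ladder(names, 1.0)))
    rest = [f"species_{i:03d}" for i in range(idx, n_species)]
    clades.append(Clade(name="background", length=0.0, children=_ladder(rest, 1.0)))
    return Clade(name="root", children=clades)


# ---------------------------------------------------------------------------
# ortholog family


@dataclass
class FamilySimConfig:
    """Study conditions for the ortholog-family generator.

    Substitution probabilities are per site over a unit root-to-tip path
    (a branch of length t substitutes with probability 1-(1-p)^t, so on an
    ultrametric unit-depth tree the expected mismatch fraction versus the
    ancestor is p up to a negligible back-mutation term).  The four KKRR
    core columns never mutate at random — in the real data the core is
    under purifying selection except in the knockout lineages, which is
    the signal the classifier must find — knockout clades instead carry
    the configured replacement motif.
    """

    tree: Clade = field(default_factory=fixture_tree)
    p_background: float = 0.2
    p_hat: float = 0.02
    p_nls: float = 0.05
    knockouts: tuple[tuple[str, str], ...] = (
        ("castorimorpha", "KKRW"),
        ("kangaroo_rats", "KKRL"),
        ("odontoceti", "KNRW"),
    )
    indel_rate: float = 0.0  # per-tip probability of one short deletion
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_background, self.p_hat, self.p_nls):
            if not 0 <= p <= 1:
                raise ValueError("substitution probabilities must lie in [0, 1]")
        for clade, motif in self.knockouts:
            if self.tree.find(clade) is None:
                raise ValueError(f"knockout clade {clade!r} not in tree")
            if len(motif) != 4:
                raise ValueError(f"knockout motif {motif!r} must have length 4")


def _site_probabilities(cfg: FamilySimConfig) -> np.ndarray:
    p = np.full(112, cfg.p_background)
    for dom, rate in ((HAT1, cfg.p_hat), (HAT2, cfg.p_hat), (NLS, cfg.p_nls)):
        p[dom.start - 1 : dom.end] = rate
    p[KKRR.start - 1 : KKRR.end] = 0.0  # protected core
    return p


def _ancestral_sequence(rng: np.random.Generator) -> str:
    seq = list(rng.choice(_AA, size=112))
    seq[NLS.start - 1 : NLS.end] = list(NLS_ANCESTRAL)
    return "".join(seq)


def simulate_family(cfg: FamilySimConfig) -> tuple[OrthologAlignment, pd.DataFrame]:
    """Evolve a pro-domain family down the species tree.

    Returns the alignment (reference row included, carrying the unmutated
    ancestor) and a per-species truth table with clade membership, the
    planted motif, the expected motif class and the per-domain
    substitution probability actually applied.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = _ancestral_sequence(rng)
    site_p = _site_probabilities(cfg)
    knockout_tips: dict[str, str] = {}
    for clade, motif in cfg.knockouts:
        for tip in cfg.tree.find(clade).tips():
            knockout_tips[tip.name] = motif  # later entries override outer clades

    rows = [
        AlignmentRow(
            sequence_id=REFERENCE_ID,
            species="Homo sapiens ref",
            accession="REF",
            isoform="1",
            residues=ancestor,
        )
    ]
    truth_records = []

    def evolve(node: Clade, seq: np.ndarray) -> None:
        seq = seq.copy()
        if node.length > 0:
            p_branch = 1.0 - (1.0 - site_p) ** node.length
            mutate = rng.random(112) < p_branch
            for i in np.flatnonzero(mutate):
                alternatives = [a for a in _AA if a != seq[i]]
                seq[i] = alternatives[rng.integers(len(alternatives))]
        if node.is_tip:
            tip_seq = seq.copy()
            motif = knockout_tips.get(node.name)
            if motif is not None:
                tip_seq[KKRR.start - 1 : KKRR.end] = list(motif)
            residues = "".join(tip_seq)
            if cfg.indel_rate > 0 and rng.random() < cfg.indel_rate:
                # one short deletion outside the annotated domains
                start = int(rng.integers(36, 70))
                width = int(rng.integers(1, 4))
                residues = residues[:start] + "-" * width + residues[start + width :]
            rows.append(
                AlignmentRow(
                    sequence_id=f"{node.name}|SIM{len(rows):04d}|1",
                    species=node.name.replace("_", " "),
                    accession=f"SIM{len(rows):04d}",
                    isoform="1",
                    residues=residues,
                )
            )
            truth_records.append(
                {
                    "species": node.name.replace("_", " "),
                    "tip": node.name,
                    "motif": motif or "KKRR",
                    "expected_class": "loss" if motif is not None else "intact",
                    "is_knockout": motif is not None,
                }
            )
        else:
            for child in node.children:
                evolve(child, seq)

    evolve(cfg.tree, np.array(list(ancestor)))
    truth = pd.DataFrame.from_records(truth_records).set_index("species")
    return OrthologAlignment(rows), truth


# ---------------------------------------------------------------------------
# sequencing reads


def default_exon(length: int = 240, motif_start: int = 100) -> tuple[str, tuple[int, int]]:
    """Deterministic synthetic exon with the motif codons planted.

    Returns the sequence and the 0-based half-open motif interval.  The
    flanks come from a fixed-seed generator, so the exon is a constant of
    the package.
    """
    rng = np.random.default_rng(20240808)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    motif = MOTIF_NT.upper()
    seq[motif_start : motif_start + len(motif)] = list(motif)
    return "".join(seq), (motif_start, motif_start + len(motif))


@dataclass
class ReadSimConfig:
    """Study conditions for the read generator."""

    reference: str = ""
    variants: tuple[tuple[int, str], ...] = ()  # (0-based position, base)
    read_length: int = 100
    read_count: int = 200
    error_rate: float = 0.01
    reverse_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference:
            self.reference = default_exon()[0]
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")
        for pos, base in self.variants:
            if not 0 <= pos < len(self.reference):
                raise ValueError(f"variant position {pos} outside reference")
            if base.upper() not in "ACGT":
                raise ValueError(f"bad variant base {base!r}")
        if self.read_length > len(self.reference):
            raise ValueError("read length exceeds reference length")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_reads(cfg: ReadSimConfig) -> tuple[list[tuple[str, str]], dict]:
    """Sample reads uniformly over the variant-applied reference.

    Per-base errors replace the true base by one of the three others
    uniformly; a configured fraction of reads is reverse-complemented.
    Returns ``(reads, truth)`` where reads are (id, sequence) pairs and
    truth records the mutated reference and variant positions.
    """
    rng = np.random.default_rng(cfg.seed)
    template = list(cfg.reference.upper())
    for pos, base in cfg.variants:
        template[pos] = base.upper()
    template = "".join(template)
    bases = "ACGT"
    reads = []
    max_start = len(template) - cfg.read_length
    for i in range(cfg.read_count):
        start = int(rng.integers(0, max_start + 1))
        read = list(template[start : start + cfg.read_length])
        errors = rng.random(cfg.read_length) < cfg.error_rate
        for j in np.flatnonzero(errors):
            others = bases.replace(read[j], "")
            read[j] = others[rng.integers(len(others))]
        seq = "".join(read)
        if rng.random() < cfg.reverse_fraction:
            seq = seq[::-1].translate(_COMPLEMENT)
        reads.append((f"read_{i:05d}", seq))
    truth = {
        "mutated_reference": template,
        "variants": list(cfg.variants),
        "error_rate": cfg.error_rate,
    }
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# LFQ matrix


@dataclass
class LfqSimConfig:
    """Study conditions for the LFQ-matrix generator.

    Intensities are log-normal on the log2 scale (baselines uniform over
    ``baseline_range``); enriched proteins are shifted by ``effect`` log2
    units in the target group.  Missingness is logistic in the true log2
    intensity — lower intensity, higher missing probability — mimicking
    left-censored LFQ data so the downshifted-normal imputation
    assumption is exercised.
    """

    n_proteins: int = 1000
    n_enriched: int = 50
    effect: float = 4.0
    sd: float = 0.5
    group_sizes: tuple[int, int] = (4, 4)  # (target, control)
    baseline_range: tuple[float, float] = (24.0, 32.0)
    missing_midpoint: float = 23.0  # log2 intensity with 50% missing chance
    missing_scale: float = 1.0
    contaminant_fraction: float = 0.02
    reverse_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enriched > self.n_proteins:
            raise ValueError("n_enriched exceeds n_proteins")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least 2 replicates")


def simulate_lfq(cfg: LfqSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a proteinGroups-dialect table plus the truth.

    The returned DataFrame has 'Protein IDs', per-sample 'LFQ intensity
    target_i'/'LFQ intensity control_i' columns (0 = missing, MaxQuant
    convention) and '+'-coded flag columns.  Truth lists the enriched
    protein ids and the group layout.
    """
    rng = np.random.default_rng(cfg.seed)
    n_t, n_c = cfg.group_sizes
    samples = [f"target_{i + 1}" for i in range(n_t)] + [
        f"control_{i + 1}" for i in range(n_c)
    ]
    groups = {s: ("target" if s.startswith("target") else "control") for s in samples}

    lo, hi = cfg.baseline_range
    baseline = rng.uniform(lo, hi, size=cfg.n_proteins)
    enriched_idx = rng.choice(cfg.n_proteins, size=cfg.n_enriched, replace=False)
    true_log2 = np.tile(baseline[:, None], (1, n_t + n_c))
    true_log2[enriched_idx, :n_t] += cfg.effect
    log2 = true_log2 + rng.normal(0.0, cfg.sd, size=true_log2.shape)

    p_missing = 1.0 / (1.0 + np.exp((log2 - cfg.missing_midpoint) / cfg.missing_scale))
    missing = rng.random(log2.shape) < p_missing
    intensities = np.where(missing, 0.0, 2.0**log2)

    ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    df = pd.DataFrame({"Protein IDs": ids})
    for j, s in enumerate(samples):
        df[f"LFQ intensity {s}"] = intensities[:, j]
    for col in ("Potential contaminant", "Reverse", "Only identified by site"):
        df[col] = ""

    n_con = int(round(cfg.contaminant_fraction * cfg.n_proteins))
    n_rev = int(round(cfg.reverse_fraction * cfg.n_proteins))
    extra = []
    for k in range(n_con + n_rev):
        row = {"Protein IDs": f"CON{k:04d}" if k < n_con else f"REV{k - n_con:04d}"}
        fake = rng.uniform(lo, hi, size=len(samples))
        for j, s in enumerate(samples):
            row[f"LFQ intensity {s}"] = 2.0 ** fake[j]
        row["Potential contaminant"] = "+" if k < n_con else ""
        row["Reverse"] = "" if k < n_con else "+"
        row["Only identified by site"] = ""
        extra.append(row)
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)

    truth = {
        "enriched_ids": sorted(ids[i] for i in enriched_idx),
        "groups": groups,
        "effect": cfg.effect,
        "samples": samples,
    }
    return df, truth
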