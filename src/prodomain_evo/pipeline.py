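"""End-to-end orchestration with a single config, seeding, and a run report.

A run is described by a YAML/dict config selecting stages and giving each
stage its parameter block.  A single global seed deterministically derives
per-stage seeds via ``numpy.random.SeedSequence((global_seed, stage_index))``
with the fixed stage enumeration in ``STAGE_IDS``, so any stage can be
re-run in isolation and two runs with the same config and seed produce
bit-identical artefacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import enrich as en
from . import readvote as rv
from . import simulate as sim
from .alignment import (
    DEFAULT_DOMAINS,
    build_reference_map,
    drop_gap_modal_columns,
    modal_consensus,
    parse_domains,
    read_alignment,
    write_alignment,
)
from .motif import call_motif, call_species_status

STAGE_IDS = {
    "simulate_family": 1,
    "consensus": 2,
    "conserve": 3,
    "motif": 4,
    "simulate_reads": 5,
    "readvote": 6,
    "simulate_lfq": 7,
    "enrich": 8,
}

DEFAULT_STAGES = list(STAGE_IDS)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: SeedSequence((global_seed, STAGE_IDS[stage]))."""
    ss = np.random.SeedSequence((global_seed, STAGE_IDS[stage]))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


class ConfigError(ValueError):
    pass


@dataclass
class RunReport:
    seed: int
    outdir: str
    stages: list[dict] = field(default_factory=list)
    completed: bool = False

    def record(self, name: str, params: dict, counts: dict, elapsed: float, warnings=()):
        self.stages.append(
            {
                "stage": name,
                "params": params,
                "counts": counts,
                "wall_clock_s": round(elapsed, 4),
                "warnings": list(warnings),
            }
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "outdir": self.outdir,
                    "completed": self.completed,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a mapping")
    return cfg


def run(config: dict, outdir: str | Path | None = None) -> RunReport:
    """Execute the selected stages in dependency order.

    Artefacts are written under ``outdir`` (or ``config['outdir']``); the
    report is serialised as ``run_report.json`` there.  A missing input
    path raises :class:`ConfigError` before any stage runs; a stage
    failure aborts downstream stages and the report records partial
    completion.
    """
    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    unknown = [s for s in stages if s not in STAGE_IDS]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    for key in ("alignment", "reads", "query"):
        path = config.get("inputs", {}).get(key)
        if path is not None and not Path(path).exists():
            raise ConfigError(f"input path does not exist: {path}")

    report = RunReport(seed=seed, outdir=str(outdir))
    state: dict = {}
    try:
        for name in sorted(stages, key=STAGE_IDS.get):
            t0 = time.perf_counter()
            params, counts, warnings = _run_stage(name, config, state, outdir, seed)
            report.record(name, params, counts, time.perf_counter() - t0, warnings)
        report.completed = True
    finally:
        report.to_json(outdir / "run_report.json")
    return report


def _run_stage(name, config, state, outdir: Path, seed: int):
    s = stage_seed(seed, name)
    warnings: list[str] = []
    if name == "simulate_family":
        block = dict(config.get("family", {}))
        tree = block.pop("tree", None)
        cfg = sim.FamilySimConfig(
            **block, seed=s, **({"tree": sim.Clade.from_dict(tree)} if tree else {})
        )
        aln, truth = sim.simulate_family(cfg)
        write_alignment(aln, outdir / "family.fasta")
        truth.to_csv(outdir / "family_truth.tsv", sep="\t")
        state["alignment"] = aln
        return (
            {"seed": s, "p_background": cfg.p_background, "p_hat": cfg.p_hat},
            {"sequences": len(aln), "species": len(aln.species)},
            warnings,
        )

    if name == "consensus":
        aln = state.get("alignment")
        if aln is None:
            aln = read_alignment(config["inputs"]["alignment"])
            state["alignment"] = aln
        consensus = modal_consensus(aln)
        filtered, retained = drop_gap_modal_columns(aln, consensus)
        reference_id = config.get("reference_id", sim.REFERENCE_ID)
        refmap = build_reference_map(aln, reference_id)
        state.update(
            consensus=consensus, filtered=filtered, retained=retained, refmap=refmap
        )
        rows = [
            {
                "column": j,
                "modal_symbol": c.symbol,
                "modal_count": c.count,
                "gap_is_modal": c.gap_is_modal,
            }
            for j, c in enumerate(consensus.columns)
        ]
        pd.DataFrame(rows).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
        return (
            {"seed": s, "reference_id": reference_id},
            {"columns": len(consensus), "retained_columns": len(retained)},
            warnings,
        )

    if name == "motif":
        aln, refmap = state["alignment"], state["refmap"]
        calls = [call_motif(r, refmap) for r in aln]
        state["motif_calls"] = {c.sequence_id: c for c in calls}
        status = call_species_status(calls)
        df = pd.DataFrame(
            [
                {
                    "species": c.species,
                    "sequence_id": c.sequence_id,
                    "motif": c.motif,
                    "class": c.motif_class.value,
                    "substitutions": ";".join(f"{p}{r}" for p, r in c.substituted_positions),
                }
                for c in calls
            ]
        )
        df.to_csv(outdir / "motif_calls.tsv", sep="\t", index=False)
        with open(outdir / "species_status.json", "w") as fh:
            json.dump(status, fh, indent=2, sort_keys=True)
        n_loss = sum(1 for v in status.values() if v == "loss")
        return ({"seed": s}, {"sequences": len(calls), "species_loss": n_loss}, warnings)

    if name == "conserve":
        aln, consensus = state["alignment"], state["consensus"]
        retained, refmap = state["retained"], state["refmap"]
        calls = state.get("motif_calls")
        if calls is None:
            calls = {r.sequence_id: call_motif(r, refmap) for r in aln}
            state["motif_calls"] = calls
        profiles = {r.sequence_id: cons.match_profile(r, consensus, retained) for r in aln}
        domains = (
            parse_domains(config["domains"]) if "domains" in config else list(DEFAULT_DOMAINS)
        )
        rows_meta = {r.sequence_id: r for r in aln}
        per_seq, summary = cons.group_summary(
            profiles, calls, domains, refmap, retained, rows=rows_meta
        )
        per_seq.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "conservation_summary.tsv", sep="\t", index=False)
        cons.barcode_table(profiles, consensus, retained).to_csv(
            outdir / "barcode.tsv", sep="\t"
        )
        return (
            {"seed": s, "domains": [d.name for d in domains]},
            {"sequences": len(profiles), "domains": len(domains)},
            warnings,
        )

    if name == "simulate_reads":
        block = dict(config.get("reads", {}))
        cfg = sim.ReadSimConfig(**block, seed=s)
        reads, truth = sim.simulate_reads(cfg)
        sim.write_fastq(reads, outdir / "reads.fastq")
        with open(outdir / "reads_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        state["reads"] = reads
        state["read_reference"] = cfg.reference
        return (
            {"seed": s, "error_rate": cfg.error_rate, "read_count": cfg.read_count},
            {"reads": len(reads)},
            warnings,
        )

    if name == "readvote":
        block = dict(config.get("readvote", {}))
        if "reads" in state:
            reads = [rv.ReadRecord(*r) for r in state["reads"]]
            query = state["read_reference"]
            interval = block.get("motif_interval", list(sim.default_exon()[1]))
        else:
            reads = rv.read_reads(config["inputs"]["reads"])
            query = rv.read_query(config["inputs"]["query"])
            interval = block["motif_interval"]
        interval = tuple(interval)
        min_score = block.get("min_score", 80)
        cap = block.get("cap", 100)
        hits = [rv.local_align(r, query) for r in reads]
        kept = rv.filter_hits(hits, min_score=min_score, cap=cap)
        table = rv.vote(kept, interval, block.get("reference_motif", rv.KKRR_CODONS.upper()),
                        query_length=len(query))
        call = rv.consensus_motif(table)
        table.table.to_csv(outdir / "vote_table.tsv", sep="\t")
        with open(outdir / "consensus_call.json", "w") as fh:
            json.dump(
                {
                    "nucleotides": call.nucleotides,
                    "amino_acids": call.amino_acids,
                    "tie_positions": list(call.tie_positions),
                    "uncovered_positions": list(call.uncovered_positions),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        return (
            {"seed": s, "min_score": min_score, "cap": cap},
            {"hits": len(hits), "kept": len(kept)},
            warnings,
        )

    if name == "simulate_lfq":
        block = dict(config.get("lfq", {}))
        cfg = sim.LfqSimConfig(**block, seed=s)
        df, truth = sim.simulate_lfq(cfg)
        df.to_csv(outdir / "proteinGroups.tsv", sep="\t", index=False)
        with open(outdir / "lfq_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        state["lfq_groups"] = truth["groups"]
        return (
            {"seed": s, "n_proteins": cfg.n_proteins, "n_enriched": cfg.n_enriched},
            {"rows": len(df)},
            warnings,
        )

    if name == "enrich":
        block = dict(config.get("enrich", {}))
        groups = state.get("lfq_groups") or block.pop("groups")
        path = (
            outdir / "proteinGroups.tsv"
            if "lfq_groups" in state
            else config["inputs"]["lfq_table"]
        )
        cfg = en.EnrichConfig(
            s0=block.get("s0", 2.0),
            fdr=block.get("fdr", 0.01),
            imputation_width=block.get("imputation_width", 0.3),
            imputation_downshift=block.get("imputation_downshift", 1.8),
            seed=s,
        )
        table = en.read_protein_groups(path, groups)
        result = en.run_enrichment(
            table, cfg, block.get("target", "target"), block.get("control", "control")
        )
        en.volcano_export(result, outdir / "enrichment.tsv")
        result.pca.coordinates.to_csv(outdir / "pca.tsv", sep="\t")
        summary = {
            "threshold_d": result.threshold_d if np.isfinite(result.threshold_d) else None,
            "pi0": result.pi0,
            "n_significant": result.n_significant,
            "n_target_enriched": result.n_target_enriched,
            "counts": result.counts,
            "s0": cfg.s0,
            "fdr": cfg.fdr,
            "seed": s,
            "explained_variance_ratio": [
                round(float(v), 6) for v in result.pca.explained_variance_ratio[:2]
            ],
        }
        with open(outdir / "enrichment_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return (
            {"seed": s, "s0": cfg.s0, "fdr": cfg.fdr},
            {
                "n_significant": result.n_significant,
                "n_target_enriched": result.n_target_enriched,
                **result.counts,
            },
            warnings,
        )

    raise ConfigError(f"unknown stage {name!r}")
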