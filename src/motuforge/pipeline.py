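"""End-to-end orchestration: distances -> trees -> delimitation ->
consensus -> conflict report -> accumulation, plus the run manifest.

``run_pipeline`` applies the whole reference-library analysis in one
call and returns a result bundle whose tables mirror the standard
outputs of a barcoding campaign: a distance-rank summary table, a
per-species barcode-gap table, one MOTU partition per method plus the
majority-rule consensus, the species-vs-MOTU conflict report, and
accumulation curves at species and MOTU level.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .accumulation import AccumulationCurve, accumulation_curve
from .consensus import ConflictReport, ConsensusResult, conflict_report, consensus_partition
from .delimitation import asap_partitions, gmyc_fit, ptp_fit, slc_cluster
from .distances import (
    DistanceMatrix,
    gap_records_frame,
    pairwise_matrix,
    rank_summaries,
    rank_summary_frame,
    species_gap_records,
)
from .errors import MotuforgeError, PipelineError
from .io_formats import ReferenceLibrary, write_partition_table
from .partition import Partition
from .trees import collapse_haplotypes, midpoint_root, nj_tree, upgma_tree, write_newick

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summarize_counts",
           "write_bundle"]

DEFAULT_METHODS = ("slc", "asap", "ptp", "gmyc")


@dataclass
class PipelineConfig:
    methods: Sequence[str] = DEFAULT_METHODS
    slc_threshold: float = 0.022
    slc_refine: bool = False
    ptp_mode: str = "auto"            # single | multi | auto (AIC)
    ptp_restarts: int = 10
    gmyc_mode: str = "single"         # single | multiple
    majority: float = 0.5
    include_morphology: bool = True   # morphology votes in the consensus
    n_permutations: int = 100
    seed: int = 0


@dataclass
class PipelineResult:
    library: ReferenceLibrary
    matrix: DistanceMatrix
    gap_records: list
    rank_summary_exclusive: dict
    rank_summary_inclusive: dict
    partitions: dict[str, Partition]
    consensus: ConsensusResult
    conflicts: ConflictReport
    accumulation_species: AccumulationCurve
    accumulation_motu: AccumulationCurve
    manifest: dict = field(default_factory=dict)


def _digest(library: ReferenceLibrary) -> str:
    h = hashlib.sha256()
    for r in library.records:
        h.update(f"{r.id}\t{r.seq}\t{r.species}\n".encode())
    return h.hexdigest()[:16]


def run_pipeline(library: ReferenceLibrary, config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    t0 = time.time()
    stage_times: dict[str, float] = {}

    def _run(stage, fn):
        t = time.time()
        try:
            out = fn()
        except MotuforgeError as exc:
            raise PipelineError(stage, str(exc)) from exc
        stage_times[stage] = round(time.time() - t, 3)
        return out

    matrix = _run("distances", lambda: pairwise_matrix(library))
    species = library.species_of()
    gaps = _run("gap_records", lambda: species_gap_records(matrix, species))
    meta = library.metadata_frame()
    rank_ex = _run("rank_summaries", lambda: rank_summaries(matrix, meta, inclusive=False))
    rank_in = rank_summaries(matrix, meta, inclusive=True)

    haplo, members = _run("haplotypes", lambda: collapse_haplotypes(library))
    hmatrix = matrix.submatrix(haplo.ids)

    partitions: dict[str, Partition] = {}
    models: dict[str, dict] = {}
    if "slc" in config.methods:
        partitions["SLC"] = _run(
            "slc",
            lambda: slc_cluster(matrix, threshold=config.slc_threshold,
                                refine=config.slc_refine),
        )
    if "asap" in config.methods:
        def _asap():
            ranked = asap_partitions(matrix)
            best = ranked[0]
            models["ASAP"] = {"threshold": best.threshold, "p_panmixia": best.p_panmixia,
                              "W": best.w, "asap_score": best.asap_score, "k": best.k}
            return best.partition
        partitions["ASAP"] = _run("asap", _asap)
    if "ptp" in config.methods:
        def _ptp():
            tree = midpoint_root(nj_tree(hmatrix))
            part, model = ptp_fit(tree, mode=config.ptp_mode,
                                  n_restarts=config.ptp_restarts, seed=config.seed)
            models[part.method] = {
                "mode": model.mode, "logL": model.logL, "aic": model.aic,
                "lrt_p": model.lrt_p, "k": model.k,
            }
            return part.expand(members)
        part = _run("ptp", _ptp)
        partitions[part.method] = part
    if "gmyc" in config.methods:
        def _gmyc():
            tree = upgma_tree(hmatrix)
            part, model = gmyc_fit(tree, mode=config.gmyc_mode, seed=config.seed)
            models[part.method] = {
                "mode": model.mode, "thresholds": model.thresholds,
                "logL": model.logL, "lrt_p": model.lrt_p, "k": model.k,
            }
            return part.expand(members)
        part = _run("gmyc", _gmyc)
        partitions[part.method] = part

    voting = list(partitions.values())
    if config.include_morphology:
        labelled = {i: sp for i, sp in species.items() if sp}
        if len(labelled) == len(species):
            voting = [Partition("MORPHOLOGY", dict(species))] + voting
        else:
            warnings.warn(
                "unidentified records present; morphology excluded from consensus"
            )
    consensus = _run("consensus", lambda: consensus_partition(voting, m=config.majority))
    conflicts = _run("conflicts", lambda: conflict_report(consensus, species, gaps))

    acc_sp = _run(
        "accumulation_species",
        lambda: accumulation_curve({i: sp for i, sp in species.items() if sp},
                                   n_permutations=config.n_permutations,
                                   seed=config.seed),
    )
    acc_motu = accumulation_curve(consensus.partition.assignment,
                                  n_permutations=config.n_permutations,
                                  seed=config.seed)

    manifest = {
        "version": __version__,
        "library_digest": _digest(library),
        "n_sequences": len(library),
        "n_species": len({s for s in species.values() if s}),
        "alignment_length": library.alignment_length,
        "parameters": {
            "methods": list(config.methods),
            "slc_threshold": config.slc_threshold,
            "slc_refine": config.slc_refine,
            "ptp_mode": config.ptp_mode,
            "ptp_restarts": config.ptp_restarts,
            "gmyc_mode": config.gmyc_mode,
            "majority": config.majority,
            "include_morphology": config.include_morphology,
            "n_permutations": config.n_permutations,
            "seed": config.seed,
        },
        "n_haplotypes": len(haplo),
        "saturated_cells": matrix.n_saturated,
        "motu_counts": {m: p.k for m, p in partitions.items()},
        "consensus_k": consensus.partition.k,
        "conflicts": {
            "splits": len(conflicts.splits),
            "lumps": len(conflicts.lumps),
            "matches": len(conflicts.matches),
        },
        "models": models,
        "stage_seconds": stage_times,
        "total_seconds": round(time.time() - t0, 3),
    }
    return PipelineResult(
        library=library, matrix=matrix, gap_records=gaps,
        rank_summary_exclusive=rank_ex, rank_summary_inclusive=rank_in,
        partitions=partitions, consensus=consensus, conflicts=conflicts,
        accumulation_species=acc_sp, accumulation_motu=acc_motu,
        manifest=manifest,
    )


def write_bundle(result: PipelineResult, outdir) -> None:
    """Write all result tables, trees-free, into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gap_records_frame(result.gap_records).to_csv(out / "gap_records.tsv", sep="\t",
                                                 index=False)
    rank_summary_frame(result.rank_summary_exclusive).to_csv(
        out / "rank_summary_exclusive.tsv", sep="\t", index=False)
    rank_summary_frame(result.rank_summary_inclusive).to_csv(
        out / "rank_summary_inclusive.tsv", sep="\t", index=False)
    write_partition_table(
        list(result.partitions.values()) + [result.consensus.partition],
        out / "partitions.tsv",
    )
    result.conflicts.to_frame().to_csv(out / "conflicts.tsv", sep="\t", index=False)
    result.accumulation_species.to_frame().to_csv(out / "accumulation_species.tsv",
                                                  sep="\t", index=False)
    result.accumulation_motu.to_frame().to_csv(out / "accumulation_motu.tsv",
                                               sep="\t", index=False)
    result.matrix.to_frame().to_csv(out / "distances.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def summarize_counts(library: ReferenceLibrary, checklist: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-order counts of families, genera, species and sequences.

    ``checklist`` (optional) is a table with columns order/families/
    genera/species giving reference richness; when given, n1/n2 columns
    and the species percentage covered are added, mirroring standard
    taxonomic-coverage tables.
    """
    meta = library.metadata_frame().replace("", "unassigned")
    grouped = meta.groupby("order").agg(
        families=("family", "nunique"),
        genera=("genus", "nunique"),
        species=("species", "nunique"),
        sequences=("sequence_id", "count"),
    ).reset_index()
    if checklist is not None:
        ref = checklist.set_index("order")
        grouped["species_checklist"] = [
            int(ref.at[o, "species"]) if o in ref.index else 0
            for o in grouped["order"]
        ]
        grouped["percent_covered"] = [
            round(100.0 * s / c, 1) if c else float("nan")
            for s, c in zip(grouped["species"], grouped["species_checklist"])
        ]
    return grouped
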