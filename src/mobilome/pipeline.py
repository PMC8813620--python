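"""End-to-end orchestration of the spacer-targeting discovery pipeline.

Stages, in order: detect arrays -> classify -> recruit -> pool & dereplicate
spacers -> mask source assemblies -> protospacer search -> collect candidate
contigs -> dereplicate contigs -> length filter -> summarize.  Every stage
hands off via files when run through the CLI; the library entry point
:func:`run_pipeline` works on in-memory records and returns the outputs plus
a :class:`RunManifest` with the auditable stage-count funnel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .catalog import (
    MgeCandidate,
    collect_candidates,
    dereplicate_contigs,
    filter_min_length,
    representatives,
    summarize_catalog,
)
from .crispr import KIND_CRISPR, classify_array, extract_spacers, find_arrays
from .io import PipelineConfig, SeqRecord, write_fasta
from .protospacer import assert_no_masked_overlap, find_protospacers, mask_arrays
from .spacerome import dereplicate_spacers, pool_spacers, recruit_arrays

logger = logging.getLogger("mobilome")


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int = 0
    funnel: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            tmp = Path(path).with_suffix(".partial")
            tmp.write_text(s)
            tmp.rename(path)  # atomic publish at run end
        return s


@dataclass
class PipelineResult:
    arrays_by_dataset: dict
    spacerome: object
    hits: list
    candidates: list[MgeCandidate]
    final: list[MgeCandidate]
    table: object
    manifest: RunManifest


def run_pipeline(
    host_assemblies: dict[str, list[SeqRecord]],
    search_assemblies: dict[str, list[SeqRecord]] | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the composed discovery procedure.

    ``host_assemblies`` maps dataset name -> contigs contributing CRISPR
    arrays (masked before the search); ``search_assemblies`` maps dataset
    name -> additional contigs searched for protospacers only.  Outputs are
    written under ``out_dir`` when given.
    """
    config = (config or PipelineConfig()).validate()
    search_assemblies = search_assemblies or {}
    funnel: dict[str, int] = {}

    # --- detect & classify -------------------------------------------------
    logger.info("stage detect-arrays")
    arrays_by_dataset: dict[str, list] = {}
    for dataset, records in host_assemblies.items():
        found = []
        for rec in records:
            for arr in find_arrays(rec, config.detector):
                classify_array(arr, params=config.detector)
                found.append(arr)
        arrays_by_dataset[dataset] = found
    all_arrays = [a for arrs in arrays_by_dataset.values() for a in arrs]
    crispr_arrays = {
        ds: [a for a in arrs if a.kind == KIND_CRISPR]
        for ds, arrs in arrays_by_dataset.items()
    }
    funnel["arrays_found"] = len(all_arrays)
    funnel["crispr_arrays"] = sum(len(v) for v in crispr_arrays.values())

    # --- recruit -----------------------------------------------------------
    logger.info("stage recruit-arrays")
    host_repeats = [
        a.consensus_repeat for arrs in crispr_arrays.values() for a in arrs
    ]
    recruited = {
        ds: recruit_arrays(
            host_repeats, arrs, config.match_min_identity, config.match_min_coverage
        )
        if host_repeats
        else []
        for ds, arrs in crispr_arrays.items()
    }
    funnel["arrays_recruited"] = sum(len(v) for v in recruited.values())

    # --- pool & dereplicate spacers -----------------------------------------
    logger.info("stage build-spacerome")
    pooled = pool_spacers(recruited)
    funnel["spacers_pooled"] = len(pooled)
    spacerome = dereplicate_spacers(pooled, config.canonicalize_strand)
    funnel["spacers_dereplicated"] = len(spacerome)

    # --- mask & search ------------------------------------------------------
    logger.info("stage find-protospacers")
    masked: list[SeqRecord] = []
    for dataset, records in host_assemblies.items():
        masked.extend(mask_arrays(records, arrays_by_dataset[dataset]))
    targets = masked + [r for recs in search_assemblies.values() for r in recs]
    hits = find_protospacers(
        spacerome,
        targets,
        min_identity=config.match_min_identity,
        min_coverage=config.match_min_coverage,
        k=config.seed_k,
        allow_gaps=config.allow_gaps,
        known_arrays=all_arrays,
    )
    assert_no_masked_overlap(hits, all_arrays)
    funnel["protospacer_hits"] = len(hits)

    # --- catalogue ----------------------------------------------------------
    logger.info("stage catalog-mges")
    candidates = collect_candidates(hits, targets)
    funnel["candidate_contigs"] = len(candidates)
    clustered = dereplicate_contigs(
        candidates, config.derep_min_identity, config.derep_min_containment
    )
    reps = representatives(clustered)
    funnel["post_dereplication"] = len(reps)
    final = filter_min_length(reps, config.mge_min_length)
    funnel["post_length_filter"] = len(final)
    table = summarize_catalog(final)

    manifest = RunManifest(config=config.to_dict(), seed=config.seed, funnel=funnel)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if final:
            write_fasta([c.contig for c in final], out / "mge_representatives.fasta")
        table.to_csv(out / "mge_catalog.tsv", sep="\t", index=False)
        with open(out / "protospacer_hits.tsv", "w") as fh:
            fh.write(
                "spacer_id\tcontig\tstart\tend\tstrand\tidentity\tquery_coverage\n"
            )
            for h in hits:
                fh.write(
                    f"{h.spacer_id}\t{h.target.contig_id}\t{h.target.start}\t"
                    f"{h.target.end}\t{h.target.strand}\t{h.identity:.4f}\t"
                    f"{h.query_coverage:.4f}\n"
                )
        manifest.to_json(out / "run_manifest.json")
    return PipelineResult(
        arrays_by_dataset=arrays_by_dataset,
        spacerome=spacerome,
        hits=hits,
        candidates=clustered,
        final=final,
        table=table,
        manifest=manifest,
    )
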