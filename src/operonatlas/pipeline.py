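"""End-to-end orchestration: ingest, merge, unify, infer, build, export.

Every numeric constant of the method lives in :class:`PipelineConfig` with
the method's published values as defaults; nothing is hard-coded in the
stages.  The run is deterministic for fixed inputs, and each dropped,
flagged, merged or inserted object leaves one structured log record.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

import yaml

from . import gff3
from .ingest import (
    IngestResult,
    ResourceConfig,
    load_resource_table,
    read_fasta_genome,
)
from .merge import DEFAULT_DO_NOT_MERGE, find_match_pairs, merge_annotations
from .model import Atlas, ModelError, check_unique_ids
from .operons import (
    DEFAULT_PATH_CAP,
    build_operons,
    build_transcript_graph,
    derive_tus_from_transcripts,
    enumerate_transcripts,
    operon_completeness,
)
from .sites import unify_sites
from .utrs import (
    TranscriptionUnit,
    associate_sites_to_genes,
    complement_tus,
    infer_flanking_utrs,
    infer_internal_utrs,
)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    ji_coding: float = 0.8
    ji_noncoding: float = 0.5
    rfam_overlap_bp: int = 40
    assoc_cutoff_bp: int = 2000
    orphan_cutoff_bp: int = 200
    min_utr_bp: int = 15
    tu_gene_overlap_frac: float = 0.70
    site_overlap_tolerance_bp: int = 25
    giant_tu_fraction: float = 0.25
    path_cap: int = DEFAULT_PATH_CAP

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ModelError(f"threshold {name} must be positive")
        for name in ("tu_gene_overlap_frac", "giant_tu_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ModelError(f"{name} must lie in (0, 1]")


@dataclass
class ResourceEntry:
    config: ResourceConfig
    table: Optional[str] = None  # path to the TSV in the ingest schema


@dataclass
class PipelineConfig:
    resources: list = field(default_factory=list)
    genome_fasta: Optional[str] = None
    genome_length: Optional[int] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    do_not_merge: frozenset = DEFAULT_DO_NOT_MERGE
    excluded_tus: frozenset = frozenset({"sigK"})
    name_preference: list = field(default_factory=list)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    resources = [
        ResourceEntry(
            config=ResourceConfig(
                name=r["name"],
                priority_rank_coding=int(r.get("priority_coding", 1)),
                priority_rank_noncoding=int(r.get("priority_noncoding", 1)),
                resolution_halfwidth=int(r.get("resolution_halfwidth", 0)),
                curated=bool(r.get("curated", False)),
            ),
            table=r.get("table"),
        )
        for r in raw.get("resources", [])
    ]
    return PipelineConfig(
        resources=resources,
        genome_fasta=raw.get("genome_fasta"),
        genome_length=raw.get("genome_length"),
        thresholds=Thresholds(**raw.get("thresholds", {})),
        do_not_merge=frozenset(raw.get("do_not_merge", DEFAULT_DO_NOT_MERGE)),
        excluded_tus=frozenset(raw.get("excluded_tus", ["sigK"])),
        name_preference=list(raw.get("name_preference", [])),
    )


def save_config(config: PipelineConfig, path) -> None:
    raw = {
        "genome_fasta": config.genome_fasta,
        "genome_length": config.genome_length,
        "thresholds": asdict(config.thresholds),
        "do_not_merge": sorted(config.do_not_merge),
        "excluded_tus": sorted(config.excluded_tus),
        "name_preference": list(config.name_preference),
        "resources": [
            {
                "name": r.config.name,
                "table": r.table,
                "priority_coding": r.config.priority_rank_coding,
                "priority_noncoding": r.config.priority_rank_noncoding,
                "resolution_halfwidth": r.config.resolution_halfwidth,
                "curated": r.config.curated,
            }
            for r in config.resources
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class PipelineResult:
    atlas: Atlas
    counts: dict
    log: list  # structured decision records, one dict per event


def _log(records: list, stage: str, action: str, obj: str, **details):
    rec = {"stage": stage, "action": action, "object": obj, **details}
    records.append(rec)
    logger.info("%s: %s %s %s", stage, action, obj, details or "")


def run_pipeline(
    config: PipelineConfig, views: Optional[Iterable[IngestResult]] = None
) -> PipelineResult:
    """Execute ingest -> gene merge -> site unification -> TU complementation
    -> UTR inference -> transcript/operon build -> classification."""
    th = config.thresholds
    records: list = []

    # --- ingest -----------------------------------------------------------
    if views is None:
        views = []
        for entry in config.resources:
            if entry.table is None:
                raise ModelError(f"resource {entry.config.name} has no table path")
            try:
                views.append(load_resource_table(entry.table, entry.config))
            except FileNotFoundError as exc:
                raise ModelError(
                    f"ingest: missing resource file {entry.table!r} "
                    f"for resource {entry.config.name}"
                ) from exc
    views = list(views)

    genome = None
    if config.genome_fasta:
        genome = read_fasta_genome(config.genome_fasta)
    genome_length = config.genome_length or (genome.length if genome else None)

    annotations, raw_sites, raw_tus = [], [], []
    for view in views:
        annotations.extend(view.annotations)
        raw_sites.extend(view.sites)
        raw_tus.extend(view.tus)
        _log(
            records, "ingest", "loaded", view.config.name,
            genes=len(view.annotations), sites=len(view.sites), tus=len(view.tus),
        )
    check_unique_ids(annotations)
    if genome_length is None:
        genome_length = max(
            [a.interval.end for a in annotations] + [s.position for s in raw_sites] + [1]
        )

    # --- gene merging ------------------------------------------------------
    pairs = find_match_pairs(
        annotations,
        ji_coding=th.ji_coding,
        ji_noncoding=th.ji_noncoding,
        do_not_merge=config.do_not_merge,
    )
    merged = merge_annotations(annotations, pairs, name_preference=config.name_preference)
    for group in merged.groups:
        _log(
            records, "merge", "merged", group.members[0].id,
            members=[m.id for m in group.members], biotype=group.merged_biotype,
        )

    # --- site unification --------------------------------------------------
    unified = unify_sites(raw_sites)
    kept_ids = {s.id for s in unified}
    for s in raw_sites:
        if s.id not in kept_ids:
            _log(records, "unify_sites", "discarded", s.id, resource=s.resource)

    # --- TU complementation ------------------------------------------------
    mapped_tus = []
    for tu in raw_tus:
        mapped = []
        for gid in tu.gene_ids:
            mid = merged.id_map.get(gid)
            if mid is None:
                raise ModelError(f"TU {tu.id} references unknown gene id {gid!r}")
            if mid not in mapped:
                mapped.append(mid)
        mapped_tus.append(
            TranscriptionUnit(
                id=tu.id, gene_ids=tuple(mapped), strand=tu.strand, region=tu.region,
                source_resources=tu.source_resources, excluded=tu.excluded,
            )
        )
    n_before = len(mapped_tus)
    tus = complement_tus(
        mapped_tus,
        merged.annotations,
        genome_length=genome_length,
        overlap_frac=th.tu_gene_overlap_frac,
        giant_fraction=th.giant_tu_fraction,
        excluded_tus=config.excluded_tus,
    )
    if len(tus) != n_before:
        _log(records, "complement_tus", "dropped_or_deduped", "tus", n=n_before - len(tus))
    for tu in tus:
        if tu.excluded:
            _log(records, "complement_tus", "excluded", tu.id)

    # --- site association and UTR inference --------------------------------
    associations, unassociated = associate_sites_to_genes(
        unified,
        merged.annotations,
        cutoff=th.assoc_cutoff_bp,
        orphan_cutoff=th.orphan_cutoff_bp,
        tus=tus,
        overlap_tolerance=th.site_overlap_tolerance_bp,
    )
    for s in unassociated:
        _log(records, "associate", "unassociated", s.id, orphan=s.orphan)
    sites_by_id = {s.id: s for s in unified}
    utrs = infer_flanking_utrs(
        associations, merged.annotations, sites_by_id, min_utr=th.min_utr_bp
    )
    utrs.extend(infer_internal_utrs(tus, merged.annotations, min_utr=th.min_utr_bp))

    # --- transcripts and operons -------------------------------------------
    genes_by_id = {g.id: g for g in merged.annotations}
    utrs_by_id = {u.id: u for u in utrs}
    transcripts = []
    dummy_sites = []
    for tu in tus:
        if tu.excluded:
            continue
        tu_graph = build_transcript_graph(tu, genes_by_id, associations, utrs, sites_by_id)
        for d in tu_graph.dummy_sites:
            dummy_sites.append(d)
            _log(records, "transcripts", "dummy_site", d.id, tu=tu.id)
        transcripts.extend(
            enumerate_transcripts(
                tu_graph, genes_by_id, sites_by_id, utrs_by_id, path_cap=th.path_cap
            )
        )
    novel_tus = derive_tus_from_transcripts(transcripts, tus, genes_by_id)
    for tu in novel_tus:
        _log(records, "transcripts", "novel_tu", tu.id, genes=list(tu.gene_ids))
    operons = build_operons(transcripts, genes_by_id)

    atlas = Atlas(
        genome=genome,
        genes=merged.annotations,
        sites=unified + dummy_sites,
        tus=tus,
        novel_tus=novel_tus,
        associations=associations,
        utrs=utrs,
        transcripts=transcripts,
        operons=operons,
    )
    counts = report_counts(atlas)
    return PipelineResult(atlas=atlas, counts=counts, log=records)


def report_counts(atlas: Atlas) -> dict:
    """Summary table: per-biotype gene counts, site/UTR/TU/transcript/operon
    counts, and per-resource site contribution/uniqueness fractions."""
    counts: dict = {}
    biotype_counts: dict = {}
    for g in atlas.genes:
        biotype_counts[g.biotype] = biotype_counts.get(g.biotype, 0) + 1
    counts["genes_total"] = len(atlas.genes)
    counts["genes_coding"] = biotype_counts.get("CDS", 0)
    counts["genes_noncoding"] = len(atlas.genes) - biotype_counts.get("CDS", 0)
    counts["genes_by_biotype"] = dict(sorted(biotype_counts.items()))

    real_sites = [s for s in atlas.sites if not s.dummy]
    counts["n_tss"] = sum(1 for s in real_sites if s.site_type == "TSS")
    counts["n_tts"] = sum(1 for s in real_sites if s.site_type == "TTS")

    utr_counts = {"five_prime": 0, "three_prime": 0, "internal": 0}
    for u in atlas.utrs:
        utr_counts[u.utr_class] += 1
    counts["utrs_by_class"] = utr_counts
    counts["utrs_total"] = sum(utr_counts.values())

    counts["n_tus"] = len(atlas.tus)
    counts["n_novel_tus"] = len(atlas.novel_tus)
    counts["n_transcripts"] = len(atlas.transcripts)

    op_classes = {"simple": 0, "traditional": 0, "complex": 0}
    for op in atlas.operons:
        op_classes[op.operon_class] += 1
    counts["operons_by_class"] = op_classes
    counts["operons_total"] = len(atlas.operons)
    counts["operons_monocistronic"] = sum(
        1 for op in atlas.operons if len(op.gene_ids) == 1
    )
    counts["operons_polycistronic"] = sum(
        1 for op in atlas.operons if len(op.gene_ids) >= 2
    )
    covered = set()
    for op in atlas.operons:
        covered.update(op.gene_ids)
    counts["gene_coverage"] = (
        len(covered) / len(atlas.genes) if atlas.genes else 0.0
    )
    counts["operon_completeness"] = operon_completeness(atlas.operons, atlas.transcripts)

    # per-resource site provenance: contribution = sites the resource supports,
    # uniqueness = sites only that resource annotated (within resolution)
    contribution: dict = {}
    unique: dict = {}
    n_real = len(real_sites)
    for s in real_sites:
        resources = {s.resource}
        for key in ("merged_sites", "collapsed_with"):
            resources.update(r for _, r in s.meta.get(key, ()))
        resources.discard("discarded")
        for r in resources:
            contribution[r] = contribution.get(r, 0) + 1
        if len(resources) == 1:
            r = next(iter(resources))
            unique[r] = unique.get(r, 0) + 1
    counts["site_contribution_frac"] = {
        r: n / n_real for r, n in sorted(contribution.items())
    } if n_real else {}
    counts["site_unique_frac"] = {
        r: n / n_real for r, n in sorted(unique.items())
    } if n_real else {}
    return counts


def export_gff3(result: PipelineResult, path) -> None:
    gff3.write_gff3(result.atlas, path)
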