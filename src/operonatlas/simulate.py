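"""Synthetic multi-resource annotation sets with known ground truth.

The generator lays non-overlapping operons on a random genome, each with its
gene chain, primary TSS/TTS (optionally with 5'/3' UTRs), optional internal
sites creating alternative isoforms, and the implied UTR/transcript/operon
truth, computed analytically from the placed sites (independent of the
pipeline's graph machinery).  Per-resource views then re-express the truth
with controlled coordinate jitter, grid snapping, resolution windows,
dropout and redundancy, emulating a curated database, a tiling-array study
and a homology screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .ingest import IngestResult, ResourceConfig
from .model import Annotation, Atlas, GenomeRef, Interval, ModelError
from .sites import BoundarySite
from .utrs import TranscriptionUnit, UTR

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ResourceNoise:
    """Noise model of one emitted resource view."""

    coordinate_jitter_sd: float = 0.0
    jitter_max: int = 0  # truncation bound for the integer Gaussian jitter
    snap_grid: int = 0  # 0 = no grid snapping; 22 emulates tiling intervals
    resolution_halfwidth: int = 0
    dropout_rate: float = 0.0
    redundancy_rate: float = 0.0
    orphan_rate: float = 0.0
    tu_interior_dropout: float = 0.0


def _default_noise() -> dict:
    return {
        "curated": ResourceNoise(tu_interior_dropout=0.3),
        "homology": ResourceNoise(
            coordinate_jitter_sd=4.0, jitter_max=10, redundancy_rate=0.6
        ),
        "tiling": ResourceNoise(
            coordinate_jitter_sd=2.0,
            jitter_max=5,
            snap_grid=22,
            resolution_halfwidth=22,
            dropout_rate=0.3,
            orphan_rate=0.2,
        ),
    }


#: Priority/resolution configuration matching the three default views.
DEFAULT_VIEW_CONFIGS = {
    "curated": ResourceConfig("curated", 1, 1, 0, curated=True),
    "homology": ResourceConfig("homology", 2, 2, 0),
    "tiling": ResourceConfig("tiling", 3, 3, 22),
}


@dataclass(frozen=True)
class TruthSpec:
    """Parameters of the synthetic genome and its noise views."""

    seed: int = 0
    genome_length: int = 400_000
    n_operons: int = 50
    genes_per_operon: tuple = (1, 4)
    cds_length: tuple = (200, 1500)
    ncrna_length: tuple = (80, 300)
    p_ncrna_operon: float = 0.15
    p_internal_utr: float = 0.5
    intra_gap_short: tuple = (2, 14)
    intra_gap_long: tuple = (15, 200)
    p_five_utr: float = 0.8
    p_three_utr: float = 0.8
    utr5_length: tuple = (15, 300)
    utr3_length: tuple = (15, 200)
    p_extra_tss: float = 0.25
    p_extra_tts: float = 0.25
    inter_operon_gap: tuple = (350, 800)
    resource_noise: dict = field(default_factory=_default_noise)

    def __post_init__(self) -> None:
        for p in (
            self.p_ncrna_operon,
            self.p_internal_utr,
            self.p_five_utr,
            self.p_three_utr,
            self.p_extra_tss,
            self.p_extra_tts,
        ):
            if not 0.0 <= p <= 1.0:
                raise ModelError("probabilities must lie in [0, 1]")
        if self.genome_length < 1000:
            raise ModelError("genome too short")


@dataclass
class TruthOperon:
    gene_ids: tuple  # transcription order
    strand: str
    n_isoforms: int
    operon_class: str
    transcripts: tuple  # (tss_id, tts_id, gene_ids) triples


@dataclass
class Truth:
    spec: TruthSpec
    genome: GenomeRef
    genes: list
    tus: list
    sites: list
    utrs: list
    operons: list

    @property
    def n_transcripts(self) -> int:
        return sum(len(op.transcripts) for op in self.operons)

    def to_atlas(self) -> Atlas:
        return Atlas(genome=self.genome, genes=list(self.genes), sites=list(self.sites),
                     tus=list(self.tus), utrs=list(self.utrs))


def _classify(n_genes: int, n_isoforms: int) -> str:
    if n_isoforms >= 2:
        return "complex"
    return "simple" if n_genes == 1 else "traditional"


def generate_truth(spec: TruthSpec) -> Truth:
    """Deterministically generate an internally consistent ground-truth atlas."""
    rng = np.random.default_rng(spec.seed)
    genes: list[Annotation] = []
    tus: list[TranscriptionUnit] = []
    sites: list[BoundarySite] = []
    utrs: list[UTR] = []
    operons: list[TruthOperon] = []

    cursor = 400 + int(rng.integers(*spec.inter_operon_gap))
    gene_counter = 0
    for k in range(spec.n_operons):
        strand = "+" if rng.random() < 0.5 else "-"
        is_nc = rng.random() < spec.p_ncrna_operon
        n = 1 if is_nc else int(rng.integers(spec.genes_per_operon[0], spec.genes_per_operon[1] + 1))

        lengths = [
            int(rng.integers(*spec.ncrna_length)) if is_nc else int(rng.integers(*spec.cds_length))
            for _ in range(n)
        ]
        gaps = [
            int(rng.integers(*spec.intra_gap_long))
            if rng.random() < spec.p_internal_utr
            else int(rng.integers(*spec.intra_gap_short))
            for _ in range(n - 1)
        ]

        # genomic layout, left to right
        op_genes: list[Annotation] = []
        pos = cursor
        for i in range(n):
            gene_counter += 1
            gid = f"g{gene_counter:04d}"
            biotype = str(rng.choice(["sRNA", "other_ncRNA"])) if is_nc else "CDS"
            op_genes.append(
                Annotation(
                    id=gid,
                    interval=Interval(pos, pos + lengths[i] - 1, strand),
                    biotype=biotype,
                    resource="truth",
                    names=frozenset({f"gene{gene_counter}"}),
                    locus_tags=frozenset({f"LT{gene_counter:04d}"}),
                )
            )
            pos += lengths[i] + (gaps[i] if i < n - 1 else 0)
        left, right = op_genes[0].interval.start, op_genes[-1].interval.end
        if right + 400 > spec.genome_length:
            raise GenerationError(
                f"infeasible packing: operon {k} would end at {right} "
                f"of a {spec.genome_length} bp genome"
            )
        genes.extend(op_genes)
        tx_genes = op_genes if strand == "+" else list(reversed(op_genes))

        # primary boundary sites
        utr5 = int(rng.integers(*spec.utr5_length)) if rng.random() < spec.p_five_utr else 0
        utr3 = int(rng.integers(*spec.utr3_length)) if rng.random() < spec.p_three_utr else 0
        tss_pos = left - utr5 if strand == "+" else right + utr5
        tts_pos = right + utr3 if strand == "+" else left - utr3
        sigma = str(rng.choice(["SigA", "SigB", "SigD", "SigW"]))
        entries = [(f"tss{k:03d}a", 0, utr5)]
        exits = [(f"tts{k:03d}a", n - 1, utr3)]
        sites.append(
            BoundarySite(
                id=entries[0][0], position=tss_pos, strand=strand, site_type="TSS",
                sigma_factors=frozenset({sigma}), resource="truth",
            )
        )
        sites.append(
            BoundarySite(
                id=exits[0][0], position=tts_pos, strand=strand, site_type="TTS",
                resource="truth",
            )
        )

        # optional internal/alternative sites creating isoforms
        if rng.random() < spec.p_extra_tss:
            i = int(rng.integers(0, n))
            if i == 0:
                alt = utr5
                while alt == utr5:
                    alt = int(rng.integers(*spec.utr5_length))
                pos_b = left - alt if strand == "+" else right + alt
                entries.append((f"tss{k:03d}b", 0, alt))
            else:
                gi = tx_genes[i].interval
                pos_b = gi.start if strand == "+" else gi.end
                entries.append((f"tss{k:03d}b", i, 0))
            sites.append(
                BoundarySite(
                    id=entries[-1][0], position=pos_b, strand=strand, site_type="TSS",
                    resource="truth",
                )
            )
        if rng.random() < spec.p_extra_tts:
            j = int(rng.integers(0, n))
            if j == n - 1:
                alt = utr3
                while alt == utr3:
                    alt = int(rng.integers(*spec.utr3_length))
                pos_b = right + alt if strand == "+" else left - alt
                exits.append((f"tts{k:03d}b", n - 1, alt))
            else:
                gj = tx_genes[j].interval
                pos_b = gj.end if strand == "+" else gj.start
                exits.append((f"tts{k:03d}b", j, 0))
            sites.append(
                BoundarySite(
                    id=exits[-1][0], position=pos_b, strand=strand, site_type="TTS",
                    resource="truth",
                )
            )

        # implied UTRs
        for sid, i, ulen in entries:
            if i == 0 and ulen >= 15:
                anchor = tx_genes[0]
                iv = (
                    Interval(anchor.interval.start - ulen, anchor.interval.start - 1, strand)
                    if strand == "+"
                    else Interval(anchor.interval.end + 1, anchor.interval.end + ulen, strand)
                )
                utrs.append(UTR(f"utr5:{sid}", iv, "five_prime", anchor.id, source_site=sid))
        for sid, j, ulen in exits:
            if j == n - 1 and ulen >= 15:
                anchor = tx_genes[-1]
                iv = (
                    Interval(anchor.interval.end + 1, anchor.interval.end + ulen, strand)
                    if strand == "+"
                    else Interval(anchor.interval.start - ulen, anchor.interval.start - 1, strand)
                )
                utrs.append(UTR(f"utr3:{sid}", iv, "three_prime", anchor.id, source_site=sid))
        for i in range(n - 1):
            a, b = op_genes[i].interval, op_genes[i + 1].interval
            gap = b.start - a.end - 1
            if gap >= 15:
                upstream, downstream = (
                    (op_genes[i].id, op_genes[i + 1].id)
                    if strand == "+"
                    else (op_genes[i + 1].id, op_genes[i].id)
                )
                utrs.append(
                    UTR(
                        f"utri:{a.end + 1}-{b.start - 1}{strand}",
                        Interval(a.end + 1, b.start - 1, strand),
                        "internal",
                        upstream,
                        next_gene=downstream,
                    )
                )

        transcripts = tuple(
            (tss_id, tts_id, tuple(g.id for g in tx_genes[i : j + 1]))
            for tss_id, i, _ in entries
            for tts_id, j, _ in exits
            if i <= j
        )
        operons.append(
            TruthOperon(
                gene_ids=tuple(g.id for g in tx_genes),
                strand=strand,
                n_isoforms=len({(t[0], t[1]) for t in transcripts}),
                operon_class=_classify(n, len(transcripts)),
                transcripts=transcripts,
            )
        )
        tus.append(
            TranscriptionUnit(
                id=f"tu{k:03d}",
                gene_ids=tuple(g.id for g in tx_genes),
                strand=strand,
                region=Interval(left, right, strand),
                source_resources=frozenset({"truth"}),
            )
        )
        cursor = right + int(rng.integers(*spec.inter_operon_gap))

    sequence = "".join(np.array(list("ACGT"))[rng.integers(0, 4, spec.genome_length)])
    genome = GenomeRef(id="synth_genome", length=spec.genome_length, sequence=sequence)
    return Truth(spec=spec, genome=genome, genes=genes, tus=tus, sites=sites, utrs=utrs,
                 operons=operons)


def _jitter(rng, value: int, noise: ResourceNoise) -> int:
    j = 0
    if noise.coordinate_jitter_sd > 0 and noise.jitter_max > 0:
        while True:
            j = int(round(rng.normal(0.0, noise.coordinate_jitter_sd)))
            if abs(j) <= noise.jitter_max:
                break
    v = value + j
    if noise.snap_grid > 1:
        v = int(round(v / noise.snap_grid)) * noise.snap_grid
    return max(1, v)


def _jitter_interval(rng, iv: Interval, noise: ResourceNoise) -> Interval:
    start = _jitter(rng, iv.start, noise)
    end = _jitter(rng, iv.end, noise)
    if end < start:
        start, end = end, start
    return Interval(start, max(end, start), iv.strand)


def emit_resource_views(truth: Truth, configs: Optional[dict] = None) -> dict:
    """Per-resource input tables emulating resource heterogeneity.

    - ``curated``: exact gene coordinates and nucleotide-resolution sites;
      TU lists with occasional interior-gene dropout.
    - ``homology``: redundant duplicates of non-coding genes with small
      jitter (Jaccard stays above the non-coding merge threshold).
    - ``tiling``: putative ncRNA predictions and sites snapped to a 22 bp
      grid with jitter, half-width 22, some orphan-flagged.
    """
    spec = truth.spec
    configs = dict(DEFAULT_VIEW_CONFIGS if configs is None else configs)
    noise = spec.resource_noise
    rng = np.random.default_rng(spec.seed + 1)

    views: dict[str, IngestResult] = {}

    # curated view: truth coordinates, all sites, TUs with interior dropout
    cur = IngestResult(config=configs["curated"])
    cur_noise = noise["curated"]
    for g in truth.genes:
        rank = (
            cur.config.priority_rank_coding if g.biotype == "CDS" else cur.config.priority_rank_noncoding
        )
        cur.annotations.append(
            Annotation(
                id=g.id, interval=g.interval, biotype=g.biotype, resource=cur.config.name,
                priority=rank, names=g.names, locus_tags=g.locus_tags,
                meta={"description": ((f"curated entry for {g.id}", cur.config.name),)},
            )
        )
    for s in truth.sites:
        cur.sites.append(
            BoundarySite(
                id=f"cur_{s.id}", position=s.position, strand=s.strand, site_type=s.site_type,
                resolution_halfwidth=0, sigma_factors=s.sigma_factors, resource=cur.config.name,
            )
        )
    for tu in truth.tus:
        gene_ids = list(tu.gene_ids)
        if len(gene_ids) >= 3 and rng.random() < cur_noise.tu_interior_dropout:
            drop = int(rng.integers(1, len(gene_ids) - 1))
            del gene_ids[drop]
        cur.tus.append(
            TranscriptionUnit(
                id=f"cur_{tu.id}", gene_ids=tuple(gene_ids), strand=tu.strand, region=tu.region,
                source_resources=frozenset({cur.config.name}),
            )
        )
    views["curated"] = cur

    # homology view: jittered duplicates of non-coding genes
    hom = IngestResult(config=configs["homology"])
    hom_noise = noise["homology"]
    for g in truth.genes:
        if g.biotype == "CDS" or rng.random() >= hom_noise.redundancy_rate:
            continue
        hom.annotations.append(
            Annotation(
                id=f"hom_{g.id}", interval=_jitter_interval(rng, g.interval, hom_noise),
                biotype=g.biotype, resource=hom.config.name,
                priority=hom.config.priority_rank_noncoding,
                names=frozenset({f"{sorted(g.names)[0]}_hom"}),
            )
        )
    views["homology"] = hom

    # tiling view: snapped putative ncRNA predictions, wide-window sites
    til = IngestResult(config=configs["tiling"])
    til_noise = noise["tiling"]
    for g in truth.genes:
        if g.biotype == "CDS" or rng.random() < til_noise.dropout_rate:
            continue
        til.annotations.append(
            Annotation(
                id=f"til_{g.id}", interval=_jitter_interval(rng, g.interval, til_noise),
                biotype="putative_ncRNA", resource=til.config.name,
                priority=til.config.priority_rank_noncoding,
            )
        )
    for s in truth.sites:
        til.sites.append(
            BoundarySite(
                id=f"til_{s.id}", position=_jitter(rng, s.position, til_noise),
                strand=s.strand, site_type=s.site_type,
                resolution_halfwidth=til.config.resolution_halfwidth,
                resource=til.config.name, orphan=bool(rng.random() < til_noise.orphan_rate),
            )
        )
    views["tiling"] = til
    return views


@dataclass
class RecoveryReport:
    """Pipeline-versus-truth comparison on a synthetic run."""

    gene_precision: float
    gene_recall: float
    site_map_jaccard: float
    utr_count_delta: dict
    transcript_count_delta: int
    operon_class_accuracy: float
    operon_confusion: dict

    @property
    def all_exact(self) -> bool:
        return (
            self.gene_precision == 1.0
            and self.gene_recall == 1.0
            and self.site_map_jaccard == 1.0
            and all(v == 0 for v in self.utr_count_delta.values())
            and self.transcript_count_delta == 0
            and self.operon_class_accuracy == 1.0
        )


def _gene_key(g: Annotation):
    return (g.interval.start, g.interval.end, g.interval.strand, g.biotype)


def score_recovery(atlas: Atlas, truth: Truth) -> RecoveryReport:
    """Exact-match recovery metrics of a pipeline output against the truth."""
    truth_genes = {_gene_key(g) for g in truth.genes}
    found_genes = {_gene_key(g) for g in atlas.genes}
    inter = truth_genes & found_genes
    precision = len(inter) / len(found_genes) if found_genes else 1.0
    recall = len(inter) / len(truth_genes) if truth_genes else 1.0

    truth_sites = {(s.site_type, s.strand, s.position) for s in truth.sites}
    found_sites = {(s.site_type, s.strand, s.position) for s in atlas.sites if not s.dummy}
    union = truth_sites | found_sites
    site_jaccard = len(truth_sites & found_sites) / len(union) if union else 1.0

    utr_delta = {}
    for cls in ("five_prime", "three_prime", "internal"):
        n_truth = sum(1 for u in truth.utrs if u.utr_class == cls)
        n_found = sum(1 for u in atlas.utrs if u.utr_class == cls)
        utr_delta[cls] = n_found - n_truth

    tx_delta = len(atlas.transcripts) - truth.n_transcripts

    genes_by_id = atlas.genes_by_id()
    found_ops = {}
    for op in atlas.operons:
        key = frozenset(
            (genes_by_id[g].interval.start, genes_by_id[g].interval.end) for g in op.gene_ids
        )
        found_ops[key] = op.operon_class
    truth_gene_iv = {g.id: g.interval for g in truth.genes}
    confusion: dict = {}
    n_correct = 0
    for top in truth.operons:
        key = frozenset((truth_gene_iv[g].start, truth_gene_iv[g].end) for g in top.gene_ids)
        predicted = found_ops.get(key, "missing")
        confusion[(top.operon_class, predicted)] = confusion.get((top.operon_class, predicted), 0) + 1
        if predicted == top.operon_class:
            n_correct += 1
    accuracy = n_correct / len(truth.operons) if truth.operons else 1.0

    return RecoveryReport(
        gene_precision=precision,
        gene_recall=recall,
        site_map_jaccard=site_jaccard,
        utr_count_delta=utr_delta,
        transcript_count_delta=tx_delta,
        operon_class_accuracy=accuracy,
        operon_confusion=confusion,
    )
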