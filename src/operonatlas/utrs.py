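"""TU complementation, site-to-gene association, and UTR inference.

A transcription unit (TU) is an ordered set of genes that can be transcribed
together, without transcript boundaries.  TUs are complemented with merged
genes they cover, TSSs/TTSs are associated to the nearest same-strand gene
5'/3' end within a distance cut-off, and gaps of at least 15 bp become
5'/3'/internal UTRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .model import (
    Annotation,
    Interval,
    ModelError,
    STRUCTURE_BIOTYPES,
    transcription_ends,
)
from .sites import BoundarySite

logger = logging.getLogger(__name__)

UTR_CLASSES = ("five_prime", "three_prime", "internal")

#: Minimum UTR length (bp); one uniform gap >= 15 rule governs the final map.
MIN_UTR_BP = 15
#: Distance cut-off for associating a site with a gene end.
ASSOC_CUTOFF_BP = 2000
#: Reduced cut-off for orphan sites (no associated transcribed region).
ORPHAN_CUTOFF_BP = 200
#: Allowed overlap of a site into its gene, to absorb resolution limits.
SITE_OVERLAP_TOLERANCE_BP = 25
#: Minimum overlap fraction (of the gene) for TU complementation rule (c).
TU_GENE_OVERLAP_FRAC = 0.70
#: TUs spanning more than this fraction of the genome are dropped as erroneous.
GIANT_TU_FRACTION = 0.25


@dataclass
class TranscriptionUnit:
    id: str
    gene_ids: tuple
    strand: str
    region: Interval
    source_resources: frozenset = frozenset()
    excluded: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        if not self.gene_ids:
            raise ModelError(f"TU {self.id} has no genes")
        self.source_resources = frozenset(self.source_resources)


@dataclass
class UTR:
    id: str
    interval: Interval
    utr_class: str
    anchor_gene: str
    source_site: Optional[str] = None
    next_gene: Optional[str] = None  # downstream gene bounding an internal UTR

    def __post_init__(self) -> None:
        if self.utr_class not in UTR_CLASSES:
            raise ModelError(f"invalid utr_class {self.utr_class!r}")
        if self.interval.length < MIN_UTR_BP:
            raise ModelError(
                f"UTR {self.id} shorter than {MIN_UTR_BP} bp ({self.interval.length})"
            )


@dataclass(frozen=True)
class SiteAssociation:
    """A site matched to a gene; gap is signed, negative meaning the site
    lies within the gene (clamped at the 25 bp tolerance)."""

    site_id: str
    gene_id: str
    site_type: str
    gap: int


def _order_in_transcription(gene_ids, genes_by_id, strand) -> tuple:
    def key(gid):
        iv = genes_by_id[gid].interval
        return (iv.start, iv.end, gid) if strand == "+" else (-iv.end, -iv.start, gid)

    return tuple(sorted(gene_ids, key=key))


def complement_tus(
    tus: Iterable[TranscriptionUnit],
    merged_genes: Iterable[Annotation],
    genome_length: int,
    overlap_frac: float = TU_GENE_OVERLAP_FRAC,
    giant_fraction: float = GIANT_TU_FRACTION,
    excluded_tus: frozenset = frozenset(),
) -> list[TranscriptionUnit]:
    """Add covered merged genes to each TU, drop giant TUs, deduplicate.

    A same-strand gene joins a TU if (a) the TU fully contains it, (b) the
    gene fully contains the TU, or (c) the overlap is at least
    ``overlap_frac`` of the gene length.  TUs spanning more than
    ``giant_fraction`` of the genome are removed as erroneous.  TUs listed in
    ``excluded_tus`` (by TU id or by a member-gene name/locus tag) are marked
    excluded but retained.
    """
    genes = list(merged_genes)
    genes_by_id = {g.id: g for g in genes}
    excluded_keys = frozenset(e.lower() for e in excluded_tus)

    out: list[TranscriptionUnit] = []
    seen_gene_sets: dict[tuple, int] = {}
    for tu in tus:
        unknown = [gid for gid in tu.gene_ids if gid not in genes_by_id]
        if unknown:
            raise ModelError(f"TU {tu.id} references unknown gene ids {unknown}")
        region = tu.region
        members = set(tu.gene_ids)
        for g in genes:
            if g.interval.strand != tu.strand or g.id in members:
                continue
            ov = region.overlap_bp(g.interval)
            if ov == 0:
                continue
            if (
                region.contains(g.interval)
                or g.interval.contains(region)
                or ov / g.interval.length >= overlap_frac
            ):
                members.add(g.id)
        ordered = _order_in_transcription(members, genes_by_id, tu.strand)
        region = Interval(
            min(genes_by_id[g].interval.start for g in ordered),
            max(genes_by_id[g].interval.end for g in ordered),
            tu.strand,
        )
        if region.length > genome_length * giant_fraction:
            logger.info("dropping giant TU %s spanning %d bp", tu.id, region.length)
            continue
        member_keys = {tu.id.lower()}
        for gid in ordered:
            member_keys |= genes_by_id[gid].name_keys()
        excluded = bool(member_keys & excluded_keys) or tu.excluded
        new = replace(tu, gene_ids=ordered, region=region, excluded=excluded)
        dedup_key = (tu.strand, ordered)
        if dedup_key in seen_gene_sets:
            prev = out[seen_gene_sets[dedup_key]]
            out[seen_gene_sets[dedup_key]] = replace(
                prev,
                source_resources=prev.source_resources | new.source_resources,
                excluded=prev.excluded or new.excluded,
            )
            logger.info("deduplicated TU %s into %s", tu.id, prev.id)
            continue
        seen_gene_sets[dedup_key] = len(out)
        out.append(new)
    return out


def _candidate_gap(
    site: BoundarySite, gene: Annotation, overlap_tolerance: int = SITE_OVERLAP_TOLERANCE_BP
) -> Optional[int]:
    """Signed distance from site to the relevant gene end, or None if the
    site is on the wrong side (beyond the overlap tolerance)."""
    ends = transcription_ends(gene.interval)
    if site.site_type == "TSS":
        anchor = ends.five_prime
        gap = anchor - site.position if gene.interval.strand == "+" else site.position - anchor
    else:
        anchor = ends.three_prime
        gap = site.position - anchor if gene.interval.strand == "+" else anchor - site.position
    if gap < -overlap_tolerance:
        return None
    return gap


def associate_sites_to_genes(
    unified_sites: Iterable[BoundarySite],
    merged_genes: Iterable[Annotation],
    cutoff: int = ASSOC_CUTOFF_BP,
    orphan_cutoff: int = ORPHAN_CUTOFF_BP,
    tus: Optional[Iterable[TranscriptionUnit]] = None,
    overlap_tolerance: int = SITE_OVERLAP_TOLERANCE_BP,
) -> tuple[list[SiteAssociation], list[BoundarySite]]:
    """Associate each TSS (TTS) to the same-strand gene with the closest
    5' (3') end within the cut-off; orphan sites use the reduced cut-off.

    Ties between equidistant genes break toward a gene that is the first
    (TSS) / last (TTS) gene of a known TU, then toward the smaller start
    coordinate.  Returns (associations, unassociated sites).
    """
    genes = list(merged_genes)
    first_of_tu: set = set()
    last_of_tu: set = set()
    if tus is not None:
        for tu in tus:
            first_of_tu.add(tu.gene_ids[0])
            last_of_tu.add(tu.gene_ids[-1])

    associations: list[SiteAssociation] = []
    unassociated: list[BoundarySite] = []
    for site in unified_sites:
        limit = orphan_cutoff if site.orphan else cutoff
        best = None
        for gene in genes:
            if gene.interval.strand != site.strand:
                continue
            gap = _candidate_gap(site, gene, overlap_tolerance)
            if gap is None or gap > limit:
                continue
            anchored = gene.id in (first_of_tu if site.site_type == "TSS" else last_of_tu)
            key = (abs(gap), 0 if anchored else 1, gene.interval.start, gene.id)
            if best is None or key < best[0]:
                best = (key, gene, gap)
        if best is None:
            unassociated.append(site)
        else:
            associations.append(
                SiteAssociation(site.id, best[1].id, site.site_type, best[2])
            )
    return associations, unassociated


def infer_flanking_utrs(
    associations: Iterable[SiteAssociation],
    merged_genes: Iterable[Annotation],
    sites_by_id: dict,
    min_utr: int = MIN_UTR_BP,
) -> list[UTR]:
    """Create 5'/3' UTRs for associations with a gap of at least 15 bp.

    When a TSS's direct association is a cis-regulatory RNA structure, the 5'
    UTR is extended downstream up to (not including) the next coding gene on
    the strand, so the structure lies inside the UTR.  Gaps below the minimum
    keep their association but produce no UTR.
    """
    genes = list(merged_genes)
    genes_by_id = {g.id: g for g in genes}
    utrs: list[UTR] = []
    for assoc in associations:
        if assoc.gap < min_utr:
            continue
        site = sites_by_id[assoc.site_id]
        gene = genes_by_id[assoc.gene_id]
        strand = gene.interval.strand
        if assoc.site_type == "TSS":
            if strand == "+":
                start, end = site.position, gene.interval.start - 1
            else:
                start, end = gene.interval.end + 1, site.position
            if gene.biotype in STRUCTURE_BIOTYPES:
                start, end = _extend_past_structure(gene, genes, start, end)
            utr_class = "five_prime"
        else:
            if strand == "+":
                start, end = gene.interval.end + 1, site.position
            else:
                start, end = site.position, gene.interval.start - 1
            utr_class = "three_prime"
        utrs.append(
            UTR(
                id=f"utr5:{assoc.site_id}" if utr_class == "five_prime" else f"utr3:{assoc.site_id}",
                interval=Interval(start, end, strand),
                utr_class=utr_class,
                anchor_gene=gene.id,
                source_site=assoc.site_id,
            )
        )
    return utrs


def _extend_past_structure(structure: Annotation, genes, start: int, end: int):
    """Extend a 5' UTR over a regulatory structure up to the next coding gene."""
    strand = structure.interval.strand
    if strand == "+":
        downstream = [
            g
            for g in genes
            if g.is_coding
            and g.interval.strand == strand
            and g.interval.start > structure.interval.start
        ]
        if not downstream:
            logger.warning(
                "no downstream coding gene for structure %s; truncating 5' UTR", structure.id
            )
            return start, structure.interval.end
        nxt = min(downstream, key=lambda g: g.interval.start)
        return start, nxt.interval.start - 1
    downstream = [
        g
        for g in genes
        if g.is_coding and g.interval.strand == strand and g.interval.end < structure.interval.end
    ]
    if not downstream:
        logger.warning(
            "no downstream coding gene for structure %s; truncating 5' UTR", structure.id
        )
        return structure.interval.start, end
    nxt = max(downstream, key=lambda g: g.interval.end)
    return nxt.interval.end + 1, end


def infer_internal_utrs(
    tus: Iterable[TranscriptionUnit],
    merged_genes: Iterable[Annotation],
    min_utr: int = MIN_UTR_BP,
) -> list[UTR]:
    """Fill >= 15 bp gaps between consecutive genes of non-excluded TUs.

    Where member genes overlap, the merged footprint (running maximum end) is
    used, so internal UTRs are never created between overlapping genes.
    Internal UTRs covering the same gap are deduplicated across TUs.
    """
    genes_by_id = {g.id: g for g in merged_genes}
    seen: dict[tuple, UTR] = {}
    out: list[UTR] = []
    for tu in tus:
        if tu.excluded:
            continue
        ordered = sorted(tu.gene_ids, key=lambda gid: genes_by_id[gid].interval.start)
        reach = None
        prev_gid = None
        for gid in ordered:
            iv = genes_by_id[gid].interval
            if reach is not None and iv.start - reach - 1 >= min_utr:
                interval = Interval(reach + 1, iv.start - 1, tu.strand)
                upstream, downstream = (prev_gid, gid) if tu.strand == "+" else (gid, prev_gid)
                key = (interval.start, interval.end, tu.strand)
                if key not in seen:
                    utr = UTR(
                        id=f"utri:{interval.start}-{interval.end}{tu.strand}",
                        interval=interval,
                        utr_class="internal",
                        anchor_gene=upstream,
                        next_gene=downstream,
                    )
                    seen[key] = utr
                    out.append(utr)
            if reach is None or iv.end > reach:
                reach = iv.end
                prev_gid = gid
    return out
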