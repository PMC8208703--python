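"""Non-redundant merging of prioritized gene/structure annotations.

Two same-strand overlapping annotations match when (i) their Jaccard index is
at least 0.8, (ii) both are non-coding and the index is at least 0.5, or
(iii) a non-coding annotation is fully contained within the other; riboswitch
overlaps with coding genes never match.  Matching pairs are closed
transitively into merge groups (across resources, priority levels, and within
one resource); each group yields one annotation with the coordinates of the
highest-priority member, or the bounding union of the members tied at the
highest priority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import (
    Annotation,
    BIOTYPE_SPECIFICITY,
    Interval,
    MetaMap,
    ModelError,
    interval_jaccard,
)

logger = logging.getLogger(__name__)

JI_CODING = 0.8
JI_NONCODING = 0.5

#: Known divergent duplicate genes kept as separate entries (lower-case
#: name/locus-tag keys); configuration, not a constant of the method.
DEFAULT_DO_NOT_MERGE = frozenset({"cott", "yoyg", "yqju", "yrzh"})


@dataclass
class MergeGroup:
    members: tuple
    kept_coordinates: Interval
    winning_priority: int
    merged_biotype: str
    merged_meta: MetaMap = field(default_factory=dict)


@dataclass
class MergeResult:
    annotations: list
    groups: list
    id_map: dict  # member id -> merged annotation id


def _is_do_not_merge_pair(a: Annotation, b: Annotation, do_not_merge) -> bool:
    """True when a and b are the two divergent entries of one listed gene."""
    shared = a.name_keys() & b.name_keys() & do_not_merge
    return bool(shared)


def find_match_pairs(
    annotations: Iterable[Annotation],
    ji_coding: float = JI_CODING,
    ji_noncoding: float = JI_NONCODING,
    do_not_merge: frozenset = DEFAULT_DO_NOT_MERGE,
) -> set:
    """All unordered pairs of annotations satisfying a match criterion."""
    anns = sorted(annotations, key=lambda a: (a.interval.start, a.interval.end, a.id))
    do_not_merge = frozenset(k.lower() for k in do_not_merge)
    pairs: set = set()
    for i, a in enumerate(anns):
        for j in range(i + 1, len(anns)):
            b = anns[j]
            if b.interval.start > a.interval.end:
                break
            if a.interval.strand != b.interval.strand:
                continue
            if a.interval.overlap_bp(b.interval) == 0:
                continue
            if {a.biotype, b.biotype} == {"riboswitch", "CDS"}:
                continue
            if _is_do_not_merge_pair(a, b, do_not_merge):
                continue
            ji = interval_jaccard(a.interval, b.interval)
            both_noncoding = not a.is_coding and not b.is_coding
            contained_noncoding = (
                (not a.is_coding and b.interval.contains(a.interval))
                or (not b.is_coding and a.interval.contains(b.interval))
            )
            if ji >= ji_coding or (both_noncoding and ji >= ji_noncoding) or contained_noncoding:
                pairs.add(frozenset((a.id, b.id)))
    return pairs


def assign_biotype(biotypes: Iterable[str]) -> str:
    """Most specific biotype of a group; asRNA over sRNA over riboswitch."""
    present = set(biotypes)
    if not present:
        raise ModelError("empty biotype group")
    specific = present - {"putative_ncRNA"}
    if "CDS" in present:
        if specific - {"CDS"}:
            raise ModelError(
                f"CDS mixed with specific non-coding biotypes in one group: {sorted(present)}"
            )
        return "CDS"
    if not specific:
        return "putative_ncRNA"
    for biotype in BIOTYPE_SPECIFICITY:
        if biotype in specific:
            return biotype
    raise ModelError(f"unorderable biotypes {sorted(specific)}")


def attach_meta(members: Iterable[Annotation], name_preference: Optional[list] = None) -> MetaMap:
    """Union of member meta maps; conflicting values are all kept with their
    origin.  ``name_preference`` orders resources for the primary name."""
    merged: dict[str, list] = {}
    for m in members:
        for key, values in m.meta.items():
            bucket = merged.setdefault(key, [])
            for pair in values:
                if pair not in bucket:
                    bucket.append(pair)
    out: MetaMap = {k: tuple(v) for k, v in merged.items()}
    if name_preference:
        ranked = sorted(
            (m for m in members if m.names),
            key=lambda m: (
                name_preference.index(m.resource)
                if m.resource in name_preference
                else len(name_preference),
                m.id,
            ),
        )
        if ranked:
            primary = sorted(ranked[0].names)[0]
            out["primary_name"] = ((primary, ranked[0].resource),)
    return out


def merge_annotations(
    annotations: Iterable[Annotation],
    pairs: set,
    name_preference: Optional[list] = None,
) -> MergeResult:
    """Collapse the transitive closure of match pairs into merged annotations.

    Singletons pass through unchanged (with provenance recorded); every
    output records its member provenance in ``meta["merged_from"]``.
    """
    anns = list(annotations)
    by_id = {a.id: a for a in anns}
    if len(by_id) != len(anns):
        raise ModelError("duplicate annotation ids in merge input")
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for pair in pairs:
        a, b = tuple(pair)
        graph.add_edge(a, b)

    merged: list = []
    groups: list = []
    id_map: dict = {}
    for component in nx.connected_components(graph):
        members = sorted(
            (by_id[i] for i in component),
            key=lambda a: (a.priority, a.interval.start, a.interval.end, a.id),
        )
        if len(members) == 1:
            only = members[0]
            id_map[only.id] = only.id
            merged.append(only)
            continue
        best_rank = members[0].priority
        tied = [m for m in members if m.priority == best_rank]
        if len(tied) == 1:
            coords = tied[0].interval
        else:
            coords = tied[0].interval
            for m in tied[1:]:
                coords = coords.bounding(m.interval)
        winner = tied[0]
        biotype = assign_biotype(m.biotype for m in members)
        meta = attach_meta(members, name_preference=name_preference)
        meta["merged_from"] = tuple((m.id, m.resource) for m in members)
        out = Annotation(
            id=winner.id,
            interval=coords,
            biotype=biotype,
            resource=winner.resource,
            priority=best_rank,
            names=frozenset().union(*(m.names for m in members)),
            locus_tags=frozenset().union(*(m.locus_tags for m in members)),
            meta=meta,
        )
        merged.append(out)
        groups.append(
            MergeGroup(
                members=tuple(members),
                kept_coordinates=coords,
                winning_priority=best_rank,
                merged_biotype=biotype,
                merged_meta=meta,
            )
        )
        for m in members:
            id_map[m.id] = out.id
        logger.info(
            "merged %d annotations into %s [%d, %d]%s",
            len(members),
            out.id,
            coords.start,
            coords.end,
            coords.strand,
        )
    merged.sort(key=lambda a: (a.interval.start, a.interval.end, a.id))
    return MergeResult(annotations=merged, groups=groups, id_map=id_map)


def merge_gene_set(
    annotations: Iterable[Annotation],
    ji_coding: float = JI_CODING,
    ji_noncoding: float = JI_NONCODING,
    do_not_merge: frozenset = DEFAULT_DO_NOT_MERGE,
    name_preference: Optional[list] = None,
) -> MergeResult:
    """Convenience: find pairs and merge in one call."""
    anns = list(annotations)
    pairs = find_match_pairs(anns, ji_coding, ji_noncoding, do_not_merge)
    return merge_annotations(anns, pairs, name_preference=name_preference)
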