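"""Unification of TSS/TTS annotations of differing resolutions.

Every boundary site carries a resolution half-width: 0 for
nucleotide-resolution (curated) sites, 22 bp for tiling-array predictions
(half of the 45 bp resolution window).  Sites of one type and strand whose
windows ``position +- halfwidth`` overlap are grouped by single linkage, and
each group keeps only the members at the group-minimal resolution; sigma
factors are inherited from the best-resolution member that has one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .model import MetaMap, ModelError

SITE_TYPES = ("TSS", "TTS")


@dataclass
class BoundarySite:
    """A transcription start (TSS) or termination (TTS) site."""

    id: str
    position: int
    strand: str
    site_type: str
    resolution_halfwidth: int = 0
    sigma_factors: frozenset = frozenset()
    resource: str = ""
    orphan: bool = False
    dummy: bool = False
    meta: MetaMap = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ModelError(f"invalid site_type {self.site_type!r}")
        if self.strand not in ("+", "-"):
            raise ModelError(f"invalid strand {self.strand!r}")
        if self.resolution_halfwidth < 0:
            raise ModelError("resolution_halfwidth must be >= 0")
        if self.dummy and (self.sigma_factors or self.resource):
            raise ModelError("dummy sites carry no sigma factor and no resource")
        self.sigma_factors = frozenset(self.sigma_factors)

    @property
    def window(self) -> tuple[int, int]:
        return (self.position - self.resolution_halfwidth, self.position + self.resolution_halfwidth)


def group_sites(sites: Iterable[BoundarySite]) -> list[list[BoundarySite]]:
    """Single-linkage groups of same-strand window-overlapping sites.

    All inputs must share one ``site_type``; TSS and TTS are unified in
    entirely separate passes.
    """
    sites = list(sites)
    types = {s.site_type for s in sites}
    if len(types) > 1:
        raise ModelError(f"mixed site types in one grouping pass: {sorted(types)}")
    groups: list[list[BoundarySite]] = []
    for strand in ("+", "-"):
        stranded = sorted(
            (s for s in sites if s.strand == strand),
            key=lambda s: (s.window[0], s.window[1], s.position, s.id),
        )
        current: list[BoundarySite] = []
        reach = None
        for s in stranded:
            lo, hi = s.window
            if current and reach is not None and lo <= reach:
                current.append(s)
                reach = max(reach, hi)
            else:
                if current:
                    groups.append(current)
                current = [s]
                reach = hi
        if current:
            groups.append(current)
    return groups


def unify_group(group: list[BoundarySite]) -> list[BoundarySite]:
    """Keep the members of a group with the minimal resolution half-width.

    Kept members at identical positions collapse to one site.  The sigma
    factor of each kept site comes from the lowest-resolution-limit member
    that has one; sigma labels of discarded members are attached as meta.
    """
    if not group:
        raise ModelError("cannot unify an empty site group")
    min_hw = min(s.resolution_halfwidth for s in group)
    kept = [s for s in group if s.resolution_halfwidth == min_hw]
    discarded = [s for s in group if s.resolution_halfwidth > min_hw]

    # best sigma source: lowest halfwidth among members that carry one
    sigma_bearers = sorted(
        (s for s in group if s.sigma_factors),
        key=lambda s: (s.resolution_halfwidth, s.position, s.id),
    )
    best_sigma = sigma_bearers[0].sigma_factors if sigma_bearers else frozenset()

    by_pos: dict[int, list[BoundarySite]] = {}
    for s in kept:
        by_pos.setdefault(s.position, []).append(s)

    out: list[BoundarySite] = []
    for pos in sorted(by_pos):
        members = by_pos[pos]
        base = min(members, key=lambda s: s.id)
        sigma = frozenset().union(*(m.sigma_factors for m in members))
        if not sigma:
            sigma = best_sigma
        meta: MetaMap = dict(base.meta)
        if discarded:
            meta["merged_sites"] = tuple((d.id, d.resource) for d in discarded)
            extra_sigma = frozenset().union(*(d.sigma_factors for d in discarded)) - sigma
            if extra_sigma:
                meta["merged_sigma"] = tuple((sf, "discarded") for sf in sorted(extra_sigma))
        if len(members) > 1:
            meta["collapsed_with"] = tuple(
                (m.id, m.resource) for m in members if m is not base
            )
        out.append(
            replace(
                base,
                sigma_factors=sigma,
                orphan=all(m.orphan for m in members),
                meta=meta,
            )
        )
    return out


def unify_sites(sites: Iterable[BoundarySite]) -> list[BoundarySite]:
    """Full unification: group and reduce TSSs and TTSs separately."""
    sites = list(sites)
    out: list[BoundarySite] = []
    for site_type in SITE_TYPES:
        of_type = [s for s in sites if s.site_type == site_type]
        for group in group_sites(of_type):
            out.extend(unify_group(group))
    out.sort(key=lambda s: (s.site_type, s.strand, s.position, s.id))
    return out


def write_sites_bed(sites: Iterable[BoundarySite], path, seqid: str = "genome") -> None:
    """BED-like 6-column export with halfwidth and sigma as extra columns."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.position, s.site_type, s.id)):
            sigma = ",".join(sorted(s.sigma_factors)) or "."
            fh.write(
                "\t".join(
                    [
                        seqid,
                        str(s.position - 1),
                        str(s.position),
                        f"{s.site_type}:{s.id}",
                        "0",
                        s.strand,
                        str(s.resolution_halfwidth),
                        sigma,
                    ]
                )
                + "\n"
            )
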