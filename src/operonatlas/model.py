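"""Core coordinate data model and interval algebra.

Coordinates are 1-based and inclusive throughout (GFF3 convention), so the
length of an interval is ``end - start + 1``.  Strands are ``"+"`` and
``"-"``.  All downstream stages (merging, site unification, UTR inference,
operon construction) operate on the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

STRANDS = ("+", "-")

#: Closed biotype vocabulary for gene/structure annotations.
BIOTYPES = frozenset(
    {
        "CDS",
        "rRNA",
        "tRNA",
        "sRNA",
        "asRNA",
        "riboswitch",
        "cis_regulatory_structure",
        "self_splicing_intron",
        "other_ncRNA",
        "putative_ncRNA",
    }
)

#: Biotypes treated as cis-regulatory RNA structures during 5' UTR extension.
STRUCTURE_BIOTYPES = frozenset({"riboswitch", "cis_regulatory_structure"})

#: Preference order used when a merge group holds conflicting specific
#: non-coding biotypes (asRNA over sRNA, sRNA over riboswitch; the remaining
#: entries give a deterministic order for combinations the method does not
#: single out).
BIOTYPE_SPECIFICITY = (
    "asRNA",
    "sRNA",
    "riboswitch",
    "rRNA",
    "tRNA",
    "cis_regulatory_structure",
    "self_splicing_intron",
    "other_ncRNA",
)


class ModelError(ValueError):
    """Raised on violations of the data-model invariants."""


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, inclusive, stranded genomic interval."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ModelError(
                f"invalid interval [{self.start}, {self.end}]: need 1 <= start <= end"
            )
        if self.strand not in STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "Interval") -> int:
        """Number of shared base pairs, ignoring strand."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "Interval") -> bool:
        """Coordinate containment (strand handled by the caller)."""
        return self.start <= other.start and other.end <= self.end

    def bounding(self, other: "Interval") -> "Interval":
        if self.strand != other.strand:
            raise ModelError("cannot bound intervals on opposite strands")
        return Interval(min(self.start, other.start), max(self.end, other.end), self.strand)


def interval_jaccard(a: Interval, b: Interval) -> float:
    """Jaccard index of two intervals over their base-pair sets.

    Opposite-strand pairs return 0 so that antisense overlaps never look
    similar: asRNA/mRNA overlaps must remain distinct features.
    """
    if a.strand != b.strand:
        return 0.0
    inter = a.overlap_bp(b)
    if inter == 0:
        return 0.0
    union = a.length + b.length - inter
    return inter / union


@dataclass(frozen=True)
class CoordinateEnds:
    """Strand-aware transcription ends of an interval."""

    five_prime: int
    three_prime: int


def transcription_ends(iv: Interval) -> CoordinateEnds:
    """5'/3' ends in transcription direction: on ``+`` the 5' end is ``start``,
    on ``-`` it is ``end``."""
    if iv.strand == "+":
        return CoordinateEnds(iv.start, iv.end)
    return CoordinateEnds(iv.end, iv.start)


@dataclass
class GenomeRef:
    """Reference sequence context (single replicon; wrap-around intervals are
    not modelled and must be pre-split)."""

    id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ModelError("genome length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ModelError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )


# meta maps key -> tuple of (value, origin-resource) pairs; conflicting values
# are all kept, each traceable to its origin.
MetaMap = dict[str, tuple[tuple[str, str], ...]]


@dataclass
class Annotation:
    """A located gene or structure from one resource (or the merged set)."""

    id: str
    interval: Interval
    biotype: str
    resource: str = ""
    priority: int = 1
    names: frozenset = frozenset()
    locus_tags: frozenset = frozenset()
    meta: MetaMap = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ModelError(f"unknown biotype {self.biotype!r} for {self.id}")
        self.names = frozenset(self.names)
        self.locus_tags = frozenset(self.locus_tags)

    @property
    def is_coding(self) -> bool:
        return self.biotype == "CDS"

    def name_keys(self) -> frozenset:
        """Lower-cased names and locus tags, for case-insensitive matching."""
        return frozenset(n.lower() for n in self.names | self.locus_tags)

    @property
    def ends(self) -> CoordinateEnds:
        return transcription_ends(self.interval)


@dataclass
class Atlas:
    """Container for one fully built annotation set.

    Fields are populated progressively by the pipeline stages; any may be
    empty.  Loosely typed on purpose: the concrete element types live in the
    stage modules.
    """

    genome: Optional[GenomeRef] = None
    genes: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    tus: list = field(default_factory=list)
    novel_tus: list = field(default_factory=list)
    associations: list = field(default_factory=list)
    utrs: list = field(default_factory=list)
    transcripts: list = field(default_factory=list)
    operons: list = field(default_factory=list)

    def genes_by_id(self) -> dict[str, Any]:
        return {g.id: g for g in self.genes}


def check_unique_ids(items, what: str = "annotation") -> None:
    seen: set = set()
    for it in items:
        if it.id in seen:
            raise ModelError(f"duplicate {what} id {it.id!r}")
        seen.add(it.id)
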