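"""Bring heterogeneous resource records into the common model.

Covers the generic TSV ingest schema, exact-sequence coordinate restoration,
sigma-site TSS derivation, name-based coordinate restoration, and filtering
of covariance-model (Rfam/Infernal) hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import Annotation, BIOTYPES, GenomeRef, Interval, ModelError
from .sites import BoundarySite
from .utrs import TranscriptionUnit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResourceConfig:
    """Identity, priority ranks and resolution of one annotation resource.

    Lower rank means higher priority; coding and non-coding annotations are
    ranked separately.  ``resolution_halfwidth`` is 0 for single-nucleotide
    resolution sites and 22 for tiling-array predictions.
    """

    name: str
    priority_rank_coding: int = 1
    priority_rank_noncoding: int = 1
    resolution_halfwidth: int = 0
    curated: bool = False

    def __post_init__(self) -> None:
        if self.priority_rank_coding < 1 or self.priority_rank_noncoding < 1:
            raise ModelError("priority ranks must be >= 1")
        if self.resolution_halfwidth < 0:
            raise ModelError("resolution_halfwidth must be >= 0")


@dataclass(frozen=True)
class RfamHit:
    family_id: str
    interval: Interval
    bit_score: float
    e_value: float
    gathering_score: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ModelError("E value must be > 0")


@dataclass(frozen=True)
class SigmaSite:
    """A sigma factor binding site, optionally with the signed offset of the
    TSS relative to the site (in transcription direction)."""

    interval: Interval
    sigma_factor: str
    offset_to_tss: Optional[int] = None


class NoMatch:
    def __repr__(self):
        return "NO_MATCH"


class Ambiguous:
    def __repr__(self):
        return "AMBIGUOUS"


NO_MATCH = NoMatch()
AMBIGUOUS = Ambiguous()
UNMATCHED = NO_MATCH


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_unique_sequence(genome: GenomeRef, query: str):
    """Find the unique exact occurrence of ``query`` on either strand.

    Returns the occurrence's :class:`Interval` (strand ``-`` when only the
    reverse complement matches), :data:`AMBIGUOUS` when two or more
    occurrences exist, or :data:`NO_MATCH`.  A palindromic (self reverse
    complementary) match at a single locus counts once: binding sites are
    double-stranded motifs.
    """
    if genome.sequence is None:
        raise ModelError("genome has no sequence")
    query = query.upper()
    if not query or set(query) - set("ACGT"):
        raise ModelError(f"query must be a non-empty ACGT string, got {query!r}")
    seq = genome.sequence.upper()
    rc = str(Seq(query).reverse_complement())
    fwd = _find_all(seq, query)
    rev = _find_all(seq, rc)
    if rc == query:
        rev = []  # identical loci; count each once, report as plus strand
    occurrences = [(i, "+") for i in fwd] + [(i, "-") for i in rev]
    if not occurrences:
        return NO_MATCH
    if len(occurrences) > 1:
        return AMBIGUOUS
    i, strand = occurrences[0]
    return Interval(i + 1, i + len(query), strand)


def tss_from_sigma_site(
    site: SigmaSite, offset_from: str = "downstream_end"
) -> Optional[BoundarySite]:
    """Derive a nucleotide-resolution TSS from a sigma binding site.

    The offset is applied in transcription direction, by default from the
    site's downstream end (``offset_from="start"`` switches to the site's
    upstream start).  Sites without an offset are skipped with a warning.
    """
    if site.offset_to_tss is None:
        logger.warning("sigma site %s has no TSS offset; skipped", site)
        return None
    iv = site.interval
    if offset_from == "downstream_end":
        anchor = iv.end if iv.strand == "+" else iv.start
    elif offset_from == "start":
        anchor = iv.start if iv.strand == "+" else iv.end
    else:
        raise ModelError(f"unknown offset convention {offset_from!r}")
    pos = anchor + site.offset_to_tss if iv.strand == "+" else anchor - site.offset_to_tss
    return BoundarySite(
        id=f"sigma_tss:{iv.start}-{iv.end}{iv.strand}",
        position=pos,
        strand=iv.strand,
        site_type="TSS",
        resolution_halfwidth=0,
        sigma_factors=frozenset({site.sigma_factor}),
        resource="sigma_sites",
    )


def match_by_name(query_names: Iterable[Iterable[str]], gene_index: Iterable[Annotation]):
    """Resolve name-sets against a gene index, case-insensitively.

    For each query name-set, returns the unique gene whose names, synonyms or
    locus tags intersect it, :data:`UNMATCHED` when no gene matches, and
    :data:`AMBIGUOUS` when two or more distinct genes do.
    """
    index: dict[str, set] = {}
    genes = {g.id: g for g in gene_index}
    for g in genes.values():
        for key in g.name_keys():
            index.setdefault(key, set()).add(g.id)
    results = []
    for names in query_names:
        hits: set = set()
        for name in names:
            hits |= index.get(name.lower(), set())
        if not hits:
            results.append(UNMATCHED)
        elif len(hits) > 1:
            results.append(AMBIGUOUS)
        else:
            results.append(genes[hits.pop()])
    return results


#: Confidence-level filters: conservative additionally requires the bit
#: score to reach the family's gathering score.
RFAM_LEVELS = {
    "conservative": (1e-6, True),
    "medium": (1e-6, False),
    "relaxed": (1e-3, False),
}


def rfam_postfilter(hits: Iterable[RfamHit], level: str = "medium") -> list[RfamHit]:
    """Filter covariance-model hits at a confidence level, then merge.

    Within the level, same-strand hits overlapping by at least 40 bp are
    clustered by single linkage; per cluster the hit with the minimal E value
    is kept, ties broken by maximal bit score.
    """
    if level not in RFAM_LEVELS:
        raise ModelError(f"unknown confidence level {level!r}")
    e_cut, require_ga = RFAM_LEVELS[level]
    kept = [
        h
        for h in hits
        if h.e_value < e_cut and (not require_ga or h.bit_score >= h.gathering_score)
    ]
    # single linkage on pairwise >= 40 bp same-strand overlap; a running
    # footprint sweep would over-merge past short non-joining hits, so the
    # components are computed from actual pairwise overlaps
    kept.sort(key=lambda h: (h.interval.start, h.interval.end, h.family_id))
    parent = list(range(len(kept)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(kept):
        for j in range(i + 1, len(kept)):
            b = kept[j]
            if b.interval.start > a.interval.end:
                break
            if b.interval.strand == a.interval.strand and a.interval.overlap_bp(b.interval) >= 40:
                parent[find(i)] = find(j)
    clusters: dict[int, list[RfamHit]] = {}
    for i, h in enumerate(kept):
        clusters.setdefault(find(i), []).append(h)
    out = [_best_hit(cluster) for cluster in clusters.values()]
    out.sort(key=lambda h: (h.interval.start, h.interval.end, h.family_id))
    return out


def _best_hit(cluster: list[RfamHit]) -> RfamHit:
    return min(
        cluster,
        key=lambda h: (h.e_value, -h.bit_score, h.interval.start, h.family_id),
    )


def read_cmsearch_tblout(path, gathering_scores: Optional[dict] = None) -> list[RfamHit]:
    """Parse Infernal ``cmsearch --tblout`` output into RfamHits.

    ``gathering_scores`` maps family id (query name) to the curated GA
    threshold; families without one default to ``+inf`` so they can never
    pass the conservative filter.
    """
    ga = gathering_scores or {}
    hits: list[RfamHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 17:
                raise ModelError(f"{path}: malformed tblout line: {line.strip()!r}")
            family = cols[2]
            lo, hi = int(cols[7]), int(cols[8])
            strand = cols[9]
            if strand == "-":
                lo, hi = hi, lo
            hits.append(
                RfamHit(
                    family_id=family,
                    interval=Interval(lo, hi, strand),
                    bit_score=float(cols[14]),
                    e_value=float(cols[15]),
                    gathering_score=float(ga.get(family, math.inf)),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# generic tabular ingest

REQUIRED_COLUMNS = ("record", "seqid", "start", "end", "strand", "id")
OPTIONAL_COLUMNS = ("biotype", "names", "locus_tags", "sigma", "orphan", "genes", "extra")
RECORD_KINDS = ("gene", "tss", "tts", "tu")


@dataclass
class IngestResult:
    config: ResourceConfig
    annotations: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    tus: list = field(default_factory=list)


def _split(cell: str) -> list[str]:
    return [v for v in str(cell).split(",") if v != ""]


def load_resource_table(path, config: ResourceConfig) -> IngestResult:
    """Load one resource's TSV into model objects.

    Schema (tab-separated, header required): ``record`` (gene|tss|tts|tu),
    ``seqid``, ``start``, ``end``, ``strand``, ``id``; optional ``biotype``,
    ``names``/``locus_tags`` (comma-separated), ``sigma``, ``orphan`` (0/1),
    ``genes`` (comma-separated gene ids, TU rows), ``extra``
    (semicolon-separated ``key=value`` pairs).  Resource name, priority and
    site resolution are stamped from ``config``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"{path}: missing required columns {missing}")
    result = IngestResult(config=config)
    for idx, row in df.iterrows():
        kind = row["record"]
        if kind not in RECORD_KINDS:
            raise ModelError(f"{path}: row {idx}: unknown record kind {kind!r}")
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise ModelError(f"{path}: row {idx}: non-integer coordinates") from exc
        strand = row["strand"]
        rid = row["id"]
        extra = {}
        for pair in str(row.get("extra", "")).split(";"):
            if "=" in pair:
                k, v = pair.split("=", 1)
                extra[k] = ((v, config.name),)
        if kind == "gene":
            biotype = row.get("biotype", "") or "putative_ncRNA"
            if biotype not in BIOTYPES:
                raise ModelError(f"{path}: row {idx}: unknown biotype {biotype!r}")
            rank = (
                config.priority_rank_coding
                if biotype == "CDS"
                else config.priority_rank_noncoding
            )
            result.annotations.append(
                Annotation(
                    id=rid,
                    interval=Interval(start, end, strand),
                    biotype=biotype,
                    resource=config.name,
                    priority=rank,
                    names=frozenset(_split(row.get("names", ""))),
                    locus_tags=frozenset(_split(row.get("locus_tags", ""))),
                    meta=extra,
                )
            )
        elif kind in ("tss", "tts"):
            sigma = frozenset(_split(row.get("sigma", "")))
            orphan = str(row.get("orphan", "")) in ("1", "true", "True")
            result.sites.append(
                BoundarySite(
                    id=rid,
                    position=start,
                    strand=strand,
                    site_type=kind.upper(),
                    resolution_halfwidth=config.resolution_halfwidth,
                    sigma_factors=sigma,
                    resource=config.name,
                    orphan=orphan,
                    meta=extra,
                )
            )
        else:  # tu
            gene_ids = _split(row.get("genes", ""))
            if not gene_ids:
                raise ModelError(f"{path}: row {idx}: TU row without genes")
            result.tus.append(
                TranscriptionUnit(
                    id=rid,
                    gene_ids=tuple(gene_ids),
                    strand=strand,
                    region=Interval(start, end, strand),
                    source_resources=frozenset({config.name}),
                )
            )
    return result


def export_resource_table(result: IngestResult, path, seqid: str = "genome") -> None:
    """Write an IngestResult back to the TSV schema (round-trip safe)."""
    rows = []
    for a in result.annotations:
        rows.append(
            {
                "record": "gene",
                "seqid": seqid,
                "start": a.interval.start,
                "end": a.interval.end,
                "strand": a.interval.strand,
                "id": a.id,
                "biotype": a.biotype,
                "names": ",".join(sorted(a.names)),
                "locus_tags": ",".join(sorted(a.locus_tags)),
                "sigma": "",
                "orphan": "",
                "genes": "",
                "extra": ";".join(f"{k}={v[0][0]}" for k, v in sorted(a.meta.items())),
            }
        )
    for s in result.sites:
        rows.append(
            {
                "record": s.site_type.lower(),
                "seqid": seqid,
                "start": s.position,
                "end": s.position,
                "strand": s.strand,
                "id": s.id,
                "biotype": "",
                "names": "",
                "locus_tags": "",
                "sigma": ",".join(sorted(s.sigma_factors)),
                "orphan": "1" if s.orphan else "0",
                "genes": "",
                "extra": "",
            }
        )
    for tu in result.tus:
        rows.append(
            {
                "record": "tu",
                "seqid": seqid,
                "start": tu.region.start,
                "end": tu.region.end,
                "strand": tu.strand,
                "id": tu.id,
                "biotype": "",
                "names": "",
                "locus_tags": "",
                "sigma": "",
                "orphan": "",
                "genes": ",".join(tu.gene_ids),
                "extra": "",
            }
        )
    pd.DataFrame(
        rows, columns=list(REQUIRED_COLUMNS[:1]) + ["seqid", "start", "end", "strand", "id"]
        + list(OPTIONAL_COLUMNS)
    ).to_csv(path, sep="\t", index=False)


def read_fasta_genome(path) -> GenomeRef:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ModelError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    return GenomeRef(id=rec.id, length=len(seq), sequence=seq)


def write_fasta_genome(genome: GenomeRef, path, width: int = 70) -> None:
    if genome.sequence is None:
        raise ModelError("genome has no sequence to write")
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")
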