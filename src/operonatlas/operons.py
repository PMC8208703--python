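"""Transcript graph construction, transcript/operon inference, classification.

Per TU, a directed acyclic graph connects TSSs, 5' UTRs, genes, internal
UTRs, 3' UTRs and TTSs in transcription direction; every TSS-to-TTS path is
one transcript.  Transcripts sharing the full sequence of at least one gene
are isoforms of one operon, found as connected components of a bipartite
transcript-gene graph.  Operons are classified as simple (one gene, one
isoform), traditional (several genes, one isoform) or complex (alternative
isoforms, regardless of gene count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import Annotation, Interval, ModelError, transcription_ends
from .sites import BoundarySite
from .utrs import SiteAssociation, TranscriptionUnit, UTR

logger = logging.getLogger(__name__)

#: Guard against path explosion in pathological TUs.
DEFAULT_PATH_CAP = 64

OPERON_CLASSES = ("simple", "traditional", "complex")


class PathExplosionError(RuntimeError):
    def __init__(self, tu_id: str, cap: int):
        super().__init__(f"TU {tu_id} exceeds the transcript path cap of {cap}")
        self.tu_id = tu_id


@dataclass
class Transcript:
    id: str
    tss_id: str
    tts_id: str
    element_ids: tuple  # ordered ("utr"|"gene", id) pairs along the path
    gene_ids: tuple
    tu_id: str
    interval: Interval
    is_mrna: bool = False

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ModelError(f"transcript {self.id} contains no genes")


@dataclass
class Operon:
    id: str
    transcript_ids: tuple
    gene_ids: tuple
    region: Interval
    operon_class: str
    n_isoforms: int = 1


@dataclass
class GuideTarget:
    """A CRISPR guide cut site with its direct and operon-expanded genes."""

    guide_id: str
    cut_position: int
    strand: str
    direct_gene: Optional[str] = None
    operon_expanded_genes: frozenset = frozenset()


@dataclass
class TuGraph:
    tu: TranscriptionUnit
    graph: nx.DiGraph
    dummy_sites: list = field(default_factory=list)


def build_transcript_graph(
    tu: TranscriptionUnit,
    genes_by_id: dict,
    associations: Iterable[SiteAssociation],
    utrs: Iterable[UTR],
    sites_by_id: dict,
) -> TuGraph:
    """Directed graph of one TU's sites, UTRs and genes.

    Edges run in transcription direction: TSS -> (5' UTR ->) gene,
    gene_i -> (internal UTR ->) gene_{i+1}, gene -> (3' UTR ->) TTS.  When no
    real TSS (TTS) is associated anywhere in the TU, a dummy site is placed
    exactly at the first (last) gene's transcription end.
    """
    order = {gid: k for k, gid in enumerate(tu.gene_ids)}
    for k in range(1, len(tu.gene_ids)):
        a = genes_by_id[tu.gene_ids[k - 1]].interval
        b = genes_by_id[tu.gene_ids[k]].interval
        fwd = b.start >= a.start if tu.strand == "+" else b.end <= a.end
        if not fwd:
            raise ModelError(f"TU {tu.id}: gene order violates coordinates")

    g = nx.DiGraph()
    for gid in tu.gene_ids:
        g.add_node(("gene", gid))

    # internal UTR chain
    internal = {
        (u.anchor_gene, u.next_gene): u
        for u in utrs
        if u.utr_class == "internal"
    }
    for k in range(1, len(tu.gene_ids)):
        prev_gid, gid = tu.gene_ids[k - 1], tu.gene_ids[k]
        utr = internal.get((prev_gid, gid))
        if utr is not None:
            g.add_edge(("gene", prev_gid), ("utr", utr.id))
            g.add_edge(("utr", utr.id), ("gene", gid))
        else:
            g.add_edge(("gene", prev_gid), ("gene", gid))

    five_by_site = {u.source_site: u for u in utrs if u.utr_class == "five_prime"}
    three_by_site = {u.source_site: u for u in utrs if u.utr_class == "three_prime"}

    have_tss = have_tts = False
    for assoc in associations:
        if assoc.gene_id not in order:
            continue
        node = ("gene", assoc.gene_id)
        if assoc.site_type == "TSS":
            have_tss = True
            utr = five_by_site.get(assoc.site_id)
            if utr is not None and utr.anchor_gene == assoc.gene_id:
                g.add_edge(("tss", assoc.site_id), ("utr", utr.id))
                g.add_edge(("utr", utr.id), node)
            else:
                g.add_edge(("tss", assoc.site_id), node)
        else:
            have_tts = True
            utr = three_by_site.get(assoc.site_id)
            if utr is not None and utr.anchor_gene == assoc.gene_id:
                g.add_edge(node, ("utr", utr.id))
                g.add_edge(("utr", utr.id), ("tts", assoc.site_id))
            else:
                g.add_edge(node, ("tts", assoc.site_id))

    dummies: list = []
    if not have_tss:
        first = genes_by_id[tu.gene_ids[0]]
        dummy = BoundarySite(
            id=f"dummy_tss:{tu.id}",
            position=transcription_ends(first.interval).five_prime,
            strand=tu.strand,
            site_type="TSS",
            dummy=True,
        )
        dummies.append(dummy)
        g.add_edge(("tss", dummy.id), ("gene", first.id))
    if not have_tts:
        last = genes_by_id[tu.gene_ids[-1]]
        dummy = BoundarySite(
            id=f"dummy_tts:{tu.id}",
            position=transcription_ends(last.interval).three_prime,
            strand=tu.strand,
            site_type="TTS",
            dummy=True,
        )
        dummies.append(dummy)
        g.add_edge(("gene", last.id), ("tts", dummy.id))
    return TuGraph(tu=tu, graph=g, dummy_sites=dummies)


def enumerate_transcripts(
    tu_graph: TuGraph,
    genes_by_id: dict,
    sites_by_id: dict,
    utrs_by_id: dict,
    path_cap: int = DEFAULT_PATH_CAP,
) -> list[Transcript]:
    """All TSS-to-TTS paths of a TU graph, as Transcripts."""
    g = tu_graph.graph
    tu = tu_graph.tu
    local_sites = dict(sites_by_id)
    for d in tu_graph.dummy_sites:
        local_sites[d.id] = d
    tss_nodes = sorted(n for n in g.nodes if n[0] == "tss")
    tts_nodes = sorted(n for n in g.nodes if n[0] == "tts")
    paths: list[list] = []
    for tss in tss_nodes:
        for tts in tts_nodes:
            for path in nx.all_simple_paths(g, tss, tts):
                paths.append(path)
                if len(paths) > path_cap:
                    raise PathExplosionError(tu.id, path_cap)

    def path_key(path):
        return tuple(path)

    paths.sort(key=path_key)
    transcripts: list[Transcript] = []
    for k, path in enumerate(paths, start=1):
        tss_id, tts_id = path[0][1], path[-1][1]
        elements = tuple(node for node in path[1:-1])
        gene_ids = tuple(nid for kind, nid in elements if kind == "gene")
        positions = [local_sites[tss_id].position, local_sites[tts_id].position]
        coding = False
        for kind, nid in elements:
            if kind == "gene":
                iv = genes_by_id[nid].interval
                coding = coding or genes_by_id[nid].is_coding
            else:
                iv = utrs_by_id[nid].interval
            positions.extend((iv.start, iv.end))
        transcripts.append(
            Transcript(
                id=f"{tu.id}.t{k}",
                tss_id=tss_id,
                tts_id=tts_id,
                element_ids=elements,
                gene_ids=gene_ids,
                tu_id=tu.id,
                interval=Interval(min(positions), max(positions), tu.strand),
                is_mrna=coding,
            )
        )
    return transcripts


def derive_tus_from_transcripts(
    transcripts: Iterable[Transcript],
    known_tus: Iterable[TranscriptionUnit],
    genes_by_id: dict,
) -> list[TranscriptionUnit]:
    """Novel TUs implied by internal TSSs/TTSs.

    A transcript's gene set that matches no known TU becomes a novel TU,
    unless an existing TU already starts (for an internal TSS) or ends (for
    an internal TTS) at the same boundary gene; duplicates collapse by gene
    set.
    """
    known = list(known_tus)
    known_sets = {(tu.strand, tu.gene_ids) for tu in known}
    starts = {tu.gene_ids[0] for tu in known}
    ends = {tu.gene_ids[-1] for tu in known}
    tu_by_id = {tu.id: tu for tu in known}

    novel: dict[tuple, TranscriptionUnit] = {}
    for tx in sorted(transcripts, key=lambda t: t.id):
        parent = tu_by_id.get(tx.tu_id)
        if parent is None:
            continue
        key = (parent.strand, tx.gene_ids)
        if key in known_sets or key in novel:
            continue
        internal_tss = tx.gene_ids[0] != parent.gene_ids[0]
        internal_tts = tx.gene_ids[-1] != parent.gene_ids[-1]
        if internal_tss and tx.gene_ids[0] in starts:
            continue
        if internal_tts and tx.gene_ids[-1] in ends:
            continue
        region = Interval(
            min(genes_by_id[g].interval.start for g in tx.gene_ids),
            max(genes_by_id[g].interval.end for g in tx.gene_ids),
            parent.strand,
        )
        novel[key] = TranscriptionUnit(
            id=f"novel_tu:{len(novel) + 1:04d}",
            gene_ids=tx.gene_ids,
            strand=parent.strand,
            region=region,
            source_resources=frozenset({"inferred"}),
        )
    return list(novel.values())


def build_operons(transcripts: Iterable[Transcript], genes_by_id: dict) -> list[Operon]:
    """Connected components of the bipartite transcript-gene graph.

    A transcript links to a gene when the gene is in its gene set and fully
    contained in its interval.
    """
    txs = list(transcripts)
    g = nx.Graph()
    for tx in txs:
        g.add_node(("tx", tx.id))
        for gid in tx.gene_ids:
            gene = genes_by_id[gid]
            if tx.interval.contains(gene.interval):
                g.add_edge(("tx", tx.id), ("g", gid))
    tx_by_id = {t.id: t for t in txs}
    components = []
    for comp in nx.connected_components(g):
        tx_ids = tuple(sorted(n[1] for n in comp if n[0] == "tx"))
        gene_ids = sorted(
            (n[1] for n in comp if n[0] == "g"),
            key=lambda gid: (genes_by_id[gid].interval.start, gid),
        )
        if not tx_ids:
            continue
        start = min(tx_by_id[t].interval.start for t in tx_ids)
        end = max(tx_by_id[t].interval.end for t in tx_ids)
        strand = tx_by_id[tx_ids[0]].interval.strand
        components.append((start, end, strand, tx_ids, tuple(gene_ids)))
    components.sort()
    operons = []
    for k, (start, end, strand, tx_ids, gene_ids) in enumerate(components, start=1):
        op = Operon(
            id=f"operon:{k:04d}",
            transcript_ids=tx_ids,
            gene_ids=gene_ids,
            region=Interval(start, end, strand),
            operon_class="simple",
        )
        op.n_isoforms = _count_isoforms(op, tx_by_id)
        op.operon_class = classify_operon(op)
        operons.append(op)
    return operons


def _count_isoforms(operon: Operon, tx_by_id: dict) -> int:
    """Isoform identity is the distinct (TSS, TTS) boundary pair."""
    return len({(tx_by_id[t].tss_id, tx_by_id[t].tts_id) for t in operon.transcript_ids})


def classify_operon(operon: Operon) -> str:
    """simple = 1 gene and 1 isoform; traditional = several genes, 1 isoform;
    complex = alternative isoforms (any gene count)."""
    if not operon.transcript_ids:
        raise ModelError(f"operon {operon.id} has no transcripts")
    if operon.n_isoforms >= 2:
        return "complex"
    return "simple" if len(operon.gene_ids) == 1 else "traditional"


def operon_completeness(operons: Iterable[Operon], transcripts: Iterable[Transcript]) -> float:
    """Fraction of operons possessing a transcript that contains every gene
    of the operon."""
    tx_by_id = {t.id: t for t in transcripts}
    ops = list(operons)
    if not ops:
        return 1.0
    n_full = 0
    for op in ops:
        genes = set(op.gene_ids)
        if any(genes <= set(tx_by_id[t].gene_ids) for t in op.transcript_ids):
            n_full += 1
    return n_full / len(ops)


def expand_offtargets_by_operon(
    targets: Iterable[GuideTarget],
    operons: Iterable[Operon],
    genes_by_id: dict,
) -> list[GuideTarget]:
    """Expand guide cut sites hitting genes of polycistronic operons to the
    full operon gene set; monocistronic or intergenic hits are unchanged."""
    operon_of_gene: dict[str, Operon] = {}
    for op in operons:
        for gid in op.gene_ids:
            operon_of_gene[gid] = op
    out: list[GuideTarget] = []
    for t in targets:
        direct = t.direct_gene
        if direct is None:
            hits = sorted(
                (
                    g.id
                    for g in genes_by_id.values()
                    if g.interval.start <= t.cut_position <= g.interval.end
                ),
                key=lambda gid: (genes_by_id[gid].interval.start, gid),
            )
            direct = hits[0] if hits else None
        if direct is None:
            expanded: frozenset = frozenset()
        else:
            op = operon_of_gene.get(direct)
            if op is not None and len(op.gene_ids) >= 2:
                expanded = frozenset(op.gene_ids)
            else:
                expanded = frozenset({direct})
        out.append(
            GuideTarget(
                guide_id=t.guide_id,
                cut_position=t.cut_position,
                strand=t.strand,
                direct_gene=direct,
                operon_expanded_genes=expanded,
            )
        )
    return out
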