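"""GFF3 reading and writing.

Reading delegates line/attribute parsing to :mod:`gffutils`; every feature row
becomes one :class:`~operonatlas.model.Annotation`, with the feature type
mapped into the closed biotype vocabulary through a configurable type map and
all attributes preserved into ``meta`` (origin = file name).

Writing emits a full atlas: genes typed by biotype, transcripts with
``Parent`` links to ``operon`` features, ``five_prime_UTR``/``three_prime_UTR``
features, and internal UTRs as type ``UTR`` with ``utr_class=internal``.
Ordering is deterministic by (start, end, id) and the body carries no
timestamps, so re-running on identical inputs is byte-identical.
"""

from __future__ import annotations

import os
import urllib.parse
from typing import Iterable, Optional

from gffutils.feature import feature_from_line

from .model import Annotation, Atlas, GenomeRef, Interval, ModelError

#: Default mapping of GFF3 feature types onto the biotype vocabulary.
#: Identity for vocabulary members, common aliases for the rest; unknown
#: types fall back to ``putative_ncRNA`` (or ``CDS`` if the caller remaps).
DEFAULT_TYPE_MAP: dict[str, str] = {
    "CDS": "CDS",
    "gene": "CDS",
    "protein_coding_gene": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "sRNA": "sRNA",
    "asRNA": "asRNA",
    "antisense_RNA": "asRNA",
    "riboswitch": "riboswitch",
    "cis_regulatory_structure": "cis_regulatory_structure",
    "self_splicing_intron": "self_splicing_intron",
    "other_ncRNA": "other_ncRNA",
    "ncRNA": "putative_ncRNA",
    "putative_ncRNA": "putative_ncRNA",
}

FALLBACK_BIOTYPE = "putative_ncRNA"

#: attributes lifted into dedicated Annotation fields rather than meta
_SPECIAL_ATTRS = ("ID", "Name", "Alias", "locus_tag")


class GFF3Error(ValueError):
    pass


def _quote(value: str) -> str:
    return urllib.parse.quote(value, safe=" :^*$@!+?|[]()/{}-_.~")


def _unquote(value: str) -> str:
    return urllib.parse.unquote(value)


def read_gff3(path, type_map: Optional[dict] = None) -> list[Annotation]:
    """Parse a GFF3 file into Annotations (1-based inclusive coordinates)."""
    tmap = DEFAULT_TYPE_MAP if type_map is None else type_map
    origin = os.path.basename(str(path))
    out: list[Annotation] = []
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise GFF3Error(f"{path}: malformed GFF3 at line {lineno}: {exc}") from exc
            if feat.start is None or feat.end is None or feat.start > feat.end:
                raise GFF3Error(
                    f"{path}: invalid coordinates at line {lineno}: "
                    f"start={feat.start} end={feat.end}"
                )
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            attrs = {k: [_unquote(v) for v in vs] for k, vs in feat.attributes.items()}
            if attrs.get("ID"):
                fid = attrs["ID"][0]
            else:
                n_anon += 1
                fid = f"{origin}:row{n_anon}"
            names = frozenset(attrs.get("Name", [])) | frozenset(attrs.get("Alias", []))
            locus_tags = frozenset(attrs.get("locus_tag", []))
            meta = {
                key: tuple((v, origin) for v in values)
                for key, values in attrs.items()
                if key not in _SPECIAL_ATTRS
            }
            meta.setdefault("source_type", ((feat.featuretype, origin),))
            out.append(
                Annotation(
                    id=fid,
                    interval=Interval(int(feat.start), int(feat.end), strand),
                    biotype=tmap.get(feat.featuretype, FALLBACK_BIOTYPE),
                    resource=origin,
                    names=names,
                    locus_tags=locus_tags,
                    meta=meta,
                )
            )
    return out


def _attr_string(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={_quote(v)}" for k, v in pairs if v != "")


def _row(seqid, source, ftype, iv: Interval, attrs: list[tuple[str, str]]) -> str:
    return "\t".join(
        [
            seqid,
            source,
            ftype,
            str(iv.start),
            str(iv.end),
            ".",
            iv.strand,
            ".",
            _attr_string(attrs),
        ]
    )


def _gene_rows(seqid, genes, gene_parents) -> Iterable[tuple]:
    for g in genes:
        attrs = [("ID", g.id)]
        if g.names:
            ordered = sorted(g.names)
            attrs.append(("Name", ordered[0]))
            if len(ordered) > 1:
                attrs.append(("Alias", ",".join(ordered[1:])))
        if g.locus_tags:
            attrs.append(("locus_tag", ",".join(sorted(g.locus_tags))))
        parents = gene_parents.get(g.id)
        if parents:
            attrs.append(("Parent", ",".join(sorted(parents))))
        for key in sorted(g.meta):
            attrs.append((key, ",".join(v for v, _ in g.meta[key])))
        yield g.interval, g.id, _row(seqid, "operonatlas", g.biotype, g.interval, attrs)


def write_gff3(atlas: Atlas, path) -> None:
    """Serialize an atlas to GFF3; raises on dangling ``Parent`` references."""
    seqid = atlas.genome.id if atlas.genome is not None else "genome"
    rows: list[tuple[Interval, str, str]] = []
    known_ids = {g.id for g in atlas.genes}

    # operon parentage for transcripts and genes
    transcript_parent: dict[str, str] = {}
    gene_parents: dict[str, set] = {}
    for op in atlas.operons:
        known_ids.add(op.id)
        for tid in op.transcript_ids:
            transcript_parent[tid] = op.id
        for gid in op.gene_ids:
            gene_parents.setdefault(gid, set()).add(op.id)
        rows.append(
            (
                op.region,
                op.id,
                _row(
                    seqid,
                    "operonatlas",
                    "operon",
                    op.region,
                    [
                        ("ID", op.id),
                        ("operon_class", op.operon_class),
                        ("n_genes", str(len(op.gene_ids))),
                        ("n_transcripts", str(len(op.transcript_ids))),
                    ],
                ),
            )
        )

    utr_parents: dict[str, set] = {}
    for tx in atlas.transcripts:
        known_ids.add(tx.id)
        attrs = [("ID", tx.id), ("tu_ref", tx.tu_id)]
        parent = transcript_parent.get(tx.id)
        if parent is not None:
            if parent not in known_ids:
                raise ModelError(f"dangling Parent {parent!r} for transcript {tx.id}")
            attrs.append(("Parent", parent))
        ftype = "mRNA" if tx.is_mrna else "transcript"
        rows.append((tx.interval, tx.id, _row(seqid, "operonatlas", ftype, tx.interval, attrs)))
        for kind, eid in tx.element_ids:
            if kind == "utr":
                utr_parents.setdefault(eid, set()).add(tx.id)

    for gid, parents in gene_parents.items():
        missing = parents - known_ids
        if missing or gid not in known_ids:
            raise ModelError(f"dangling reference for gene {gid!r}")

    rows.extend(_gene_rows(seqid, atlas.genes, gene_parents))

    for u in atlas.utrs:
        attrs = [("ID", u.id), ("anchor_gene", u.anchor_gene)]
        if u.utr_class == "five_prime":
            ftype = "five_prime_UTR"
        elif u.utr_class == "three_prime":
            ftype = "three_prime_UTR"
        else:
            ftype = "UTR"
            attrs.append(("utr_class", "internal"))
        if u.source_site:
            attrs.append(("source_site", u.source_site))
        parents = utr_parents.get(u.id)
        if parents:
            missing = parents - known_ids
            if missing:
                raise ModelError(f"dangling Parent {sorted(missing)} for UTR {u.id}")
            attrs.append(("Parent", ",".join(sorted(parents))))
        rows.append((u.interval, u.id, _row(seqid, "operonatlas", ftype, u.interval, attrs)))

    rows.sort(key=lambda r: (r[0].start, r[0].end, r[1]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if atlas.genome is not None:
            fh.write(f"##sequence-region {seqid} 1 {atlas.genome.length}\n")
        for _, _, line in rows:
            fh.write(line + "\n")


def write_genes_gff3(genes, path, genome: Optional[GenomeRef] = None) -> None:
    """Convenience: write a bare gene set (no transcripts/operons)."""
    write_gff3(Atlas(genome=genome, genes=list(genes)), path)
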