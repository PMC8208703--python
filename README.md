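# operonatlas

`operonatlas` builds a unified transcriptome annotation for a bacterial
genome out of heterogeneous, partially redundant annotation resources. It is
aimed at researchers who have gene/structure annotations, transcription
start/termination sites (TSS/TTS) and co-transcribed gene lists scattered
across curated databases, tiling-array or Term-seq studies, and covariance
model screens — and who need one non-redundant gene set, one promoter and
terminator map, explicit 5′/3′/internal UTRs, and transcript/operon
annotations, all exportable as GFF3.

## The method

**Gene merging.** For every same-strand overlapping pair of annotations the
Jaccard index over base pairs is computed, JI = |a ∩ b| / |a ∪ b|. Two
annotations match when (i) JI ≥ 0.8, (ii) both are non-coding and JI ≥ 0.5,
or (iii) a non-coding annotation is fully contained in the other;
riboswitch–CDS overlaps never match, and a configurable list of known
divergent duplicates is kept separate. Matches are closed transitively into
groups (across and within resources); each group becomes one annotation with
the coordinates of the highest-priority member — or the bounding union of
members tied at the highest priority — the most specific biotype in the
group (asRNA ≻ sRNA ≻ riboswitch; any specific biotype over a putative one),
and the union of all meta-information with per-value origins.

**Site unification.** Every TSS/TTS carries a resolution half-width (0 for
curated nucleotide-resolution sites, 22 bp for tiling-array predictions,
i.e. a 45 bp window). Sites of one type and strand whose windows overlap are
grouped by single linkage; each group keeps the sites at the group-minimal
resolution, inheriting sigma-factor labels from the best-resolution member
that has one.

**UTRs.** Each TSS (TTS) is associated with the same-strand gene with the
nearest 5′ (3′) end within 2000 bp — 200 bp for orphan sites that had no
transcribed region in their source — allowing a 25 bp overlap into the gene.
Gaps of ≥ 15 bp become 5′/3′ UTRs; a 5′ UTR whose direct association is a
cis-regulatory RNA structure is extended to the next coding gene. Gaps
≥ 15 bp between consecutive genes of a transcription unit (TU) become
internal UTRs (excluded TUs, such as the sigK region in *Bacillus subtilis*,
produce none).

**Transcripts and operons.** Per TU, a directed acyclic graph connects
TSSs → 5′ UTRs → genes → internal UTRs → … → 3′ UTRs → TTSs in transcription
direction, with dummy boundaries at terminal gene ends where no site is
associated. Every TSS-to-TTS path is a transcript; transcript gene sets not
matching any known TU yield novel TUs. Transcripts sharing the full sequence
of at least one gene are isoforms of one operon (connected components of a
bipartite transcript–gene graph). Operons are classified *simple* (one gene,
one isoform), *traditional* (several genes, one isoform) or *complex*
(alternative isoforms). Operon membership also expands CRISPR guide
off-target gene lists across polycistronic operons.

**Validation statistics.** ML2 — the mean over an annotation's positions of
the per-position maximum log2 expression signal across conditions — scores
transcription evidence, and agreement tables compare UTR class labels
between annotation sets.

## Worked example

The package ships a synthetic-data generator that lays out operons with
known gene chains, boundary sites, isoforms and UTRs, then re-expresses them
as three noisy resource views (a curated database, a homology screen with
redundant ncRNAs, a tiling-array study snapped to a 22 bp grid):

```sh
operonatlas simulate --seed 1 --n-operons 50 --out-dir demo
operonatlas report --config demo/config.yaml
```

prints (abridged):

```json
{
  "genes_total": 113,
  "genes_coding": 104,
  "genes_noncoding": 9,
  "n_tss": 62,
  "n_tts": 62,
  "n_tus": 50,
  "n_novel_tus": 7,
  "n_transcripts": 77,
  "utrs_by_class": {"five_prime": 46, "internal": 30, "three_prime": 49},
  "operons_by_class": {"complex": 21, "simple": 10, "traditional": 19},
  "operons_total": 50,
  "gene_coverage": 1.0,
  "operon_completeness": 1.0
}
```

The 113 merged genes come from three overlapping views of the same 113 true
genes — redundant duplicates collapse onto the curated coordinates. The 50
TUs gain 7 novel TUs from internal TSSs/TTSs, which also raise the
transcript count (77) above the TU count; 21 operons have alternative
isoforms and are therefore complex. `operon_completeness` is the fraction of
operons with a transcript covering all their genes. The same run can be
exported with `operonatlas export-gff3 --config demo/config.yaml --out
atlas.gff3`, and `operonatlas build-operons … --out operons.tsv` writes the
per-operon summary:

```text
id           n_genes  n_transcripts  n_isoforms  operon_class
operon:0001  1        1              1           simple
operon:0002  1        4              4           complex
operon:0003  2        2              2           complex
```

In Python, the same stages are plain functions
(`operonatlas.merge_gene_set`, `unify_sites`, `associate_sites_to_genes`,
`infer_flanking_utrs`, `build_operons`, …) over dataclasses
(`Annotation`, `BoundarySite`, `TranscriptionUnit`, `Transcript`, `Operon`).

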