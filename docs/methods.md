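# Methods

This note documents the model behind `operonatlas`, the parameters that
matter, the synthetic data it is validated on, and the numerical choices
made where the design was genuinely open.

## Data model

All coordinates are 1-based and inclusive (the GFF3 convention); the length
of an interval is `end − start + 1`, and "bp" always refers to genomic
coordinates. Strands are `+`/`−`; the 5′ end of a feature is its `start` on
the plus strand and its `end` on the minus strand. Circular-genome
wrap-around features are not modelled: none of the merging, association or
graph procedures are defined across the origin, so origin-spanning features
must be pre-split. Gene and structure records carry one biotype from a
closed vocabulary (CDS, rRNA, tRNA, sRNA, asRNA, riboswitch,
cis-regulatory structure, self-splicing intron, other ncRNA, putative
ncRNA), a resource of origin with separate coding/non-coding priority
ranks, name/locus-tag synonym sets, and a meta map whose every value keeps
its origin resource.

## Gene merging

The merge similarity is the Jaccard index of the two base-pair sets.
Opposite-strand pairs are defined to have JI 0: merging across strands would
collapse antisense RNAs onto their sense mRNAs, which must remain distinct
features. Match criteria: JI ≥ `ji_coding` (default 0.8); JI ≥
`ji_noncoding` (default 0.5) when both annotations are non-coding; or full
containment of a non-coding annotation in another feature. The containment
rule deliberately allows a non-coding annotation inside a coding gene (a
short doubtful ORF or structure absorbed by its host), while the
riboswitch–CDS exclusion keeps regulatory structures that overlap the genes
they regulate as separate features. A configurable do-not-merge list
(seeded with cotT, yoyG, yqjU, yrzH, known divergent duplicates in the
*B. subtilis* literature) blocks pairs that share a listed name.

Groups are the connected components of the match-pair graph — merging is a
single transitive step across all priority levels and within resources, not
an iterative procedure whose result would depend on merge order. Each group
takes the coordinates of its highest-priority member; when several members
tie at the best rank, the bounding interval of the *tied members only* is
used (not of the whole group, which could drag in low-confidence outliers).
Biotype assignment prefers any specific biotype over putative ncRNA, and
resolves conflicts among specific biotypes as asRNA ≻ sRNA ≻ riboswitch
(a term-seq riboswitch call under an annotated sRNA is an sRNA); a group
mixing CDS with a specific non-coding biotype indicates an upstream filter
failure and raises an integrity error. Merged meta keeps *all* conflicting
values with their origins; a resource preference order can pick the primary
display name.

Idempotence note: merging is idempotent whenever the winning coordinates
are one member's own interval. Tie-unions can in principle enlarge an
interval enough to contain a previously unmatched neighbour, so downstream
consumers should treat the merged set, not a re-merge of it, as the result.

## Site unification

Each boundary site has a resolution half-width: 0 for curated
nucleotide-resolution annotations, 22 bp for tiling-array predictions (half
of the 45 bp window implied by the ~22 bp tiling interval). TSSs and TTSs
are processed in fully separate passes, strand by strand — a + TSS and a −
TSS are never the same biological feature. Windows `position ± halfwidth`
that overlap are grouped by single linkage (for ≥ 1 bp window overlap, a
left-to-right sweep is exact). Each group keeps every member whose
half-width equals the group minimum: equal-resolution sites at distinct
positions are genuinely distinct promoters/terminators and are all
retained; only identical positions collapse. The sigma factor of a kept
site comes from the lowest-half-width member that carries one; when several
minimal-resolution members disagree, all labels are kept as a set, and
sigma labels of discarded members are preserved as meta.

## Rfam hit filtering

Covariance-model hits are filtered at three confidence levels —
conservative (E < 10⁻⁶ and bit score ≥ the family's gathering score),
medium (E < 10⁻⁶), relaxed (E < 10⁻³) — then same-strand hits overlapping
by ≥ 40 bp are clustered. Clustering is single linkage over *pairwise*
overlaps computed exactly: a running-footprint sweep would over-merge past
short non-joining hits, so components are built from the actual pairwise
≥ 40 bp relation. Per cluster the hit with the minimal E value survives,
ties broken by maximal bit score, then by coordinate for determinism.
Families without a known gathering score default to +∞ so they can never
pass the conservative filter by accident.

## Coordinate restoration

Binding-site sequences are located by exact search of both strands; a match
is used only if it is unique genome-wide, where a self-reverse-complementary
(palindromic) sequence found at one locus counts as one occurrence — binding
sites are double-stranded motifs. TSSs derived from sigma-factor sites are
placed at the site's downstream end shifted by the annotated offset in
transcription direction; because source databases do not document whether
offsets are anchored at the site start or its downstream end, the anchor is
a config switch (`offset_from`), defaulting to the downstream end.
Name-based restoration matches query synonym sets case-insensitively
against merged gene names and locus tags, keeping only unique hits and
reporting unmatched/ambiguous outcomes as data, not errors.

## TU complementation, association, UTRs

A TU gains every same-strand merged gene that is (a) contained in the TU
region, (b) containing it, or (c) overlapping by ≥ 70 % of the gene length;
gene order is then recomputed in transcription direction and TUs spanning
more than a quarter of the genome are dropped as curation errors. TUs with
identical gene sets are deduplicated (their source resources merged), and
config-listed TUs (default: any TU containing a gene named sigK) are marked
excluded — retained for bookkeeping but barred from internal-UTR,
transcript and operon inference, because the region inside the sigK TU is
physically excised rather than transcribed.

A TSS associates with the same-strand gene whose 5′ end is nearest within
2000 bp (orphan sites: 200 bp), where "nearest" minimises the absolute
signed gap and sites may reach up to 25 bp into the gene to absorb
resolution limits; TTSs mirror this with 3′ ends. The signed gap equals the
coordinate difference, so a gap of *g* implies a *g* bp UTR; ties between
equidistant genes break toward a gene that begins (TSS) / ends (TTS) a
known TU, then toward the smaller start coordinate. One uniform rule
`gap ≥ 15 bp` governs all three UTR classes (the minimum credible UTR
length; shorter gaps are within site-resolution noise). A 5′ association
landing on a cis-regulatory structure (riboswitch or similar) extends the
UTR downstream to the next coding gene — the structure is part of the
messenger's leader — while the structure remains the association anchor.
Internal UTRs fill ≥ 15 bp gaps between consecutive TU genes, measured on
the merged footprint where member genes overlap (never between overlapping
genes), and identical gaps are emitted once across TUs.

## Transcript and operon inference

Per TU, nodes are the TU's genes, their associated sites, and the UTRs
between them; directed edges follow transcription. A dummy TSS (TTS) is
inserted exactly at the first (last) gene's transcription end when no real
site is associated anywhere in the TU on that side; dummy-bounded
transcripts have no UTR on that side. Each TSS→TTS path is one transcript;
a path cap (default 64 per TU) guards against pathological site pile-ups
and fails loudly naming the TU. Transcript gene sets not present among
known TUs become novel TUs, unless a known TU already starts (internal TSS)
or ends (internal TTS) at the same boundary gene — in that case the
apparent novel unit is just the adjacent known unit.

Operons are connected components of the bipartite graph linking each
transcript to the genes it fully contains. Isoform identity is the distinct
(TSS, TTS) boundary pair — not the gene set — so a single gene with two
alternative 5′ UTR lengths forms a complex monocistronic operon, which the
gene-set definition would miss. Classes: simple (1 gene, 1 isoform),
traditional (≥ 2 genes, 1 isoform), complex (≥ 2 isoforms). Guide
off-target expansion maps a cut position to its containing gene and, when
that gene sits in a polycistronic operon, to all the operon's genes,
reflecting that interference suppresses the whole message.

## Evidence statistics

ML2 of an annotation is the mean over its positions of the per-position
maximum log2 signal across all conditions. Signals are taken as-is — no
normalization is applied, matching the recommendation for the array design
the statistic was conceived for. Summary percentiles (the value exceeded by
90 % of annotations, and the median) use linear interpolation, and the
method is declared in the output so thresholds quoted from it are
unambiguous. UTR biotype agreement counts each source UTR once: agreement
if any same-strand ≥ 1 bp overlap with a target of equal class exists; a
dedicated cell for sources overlapping both a 5′ and a 3′ target; otherwise
the overlapped class, or "no overlap". No minimum overlap beyond 1 bp is
imposed.

## Synthetic data

The generator places `n_operons` (default 50) non-overlapping operons on a
random genome (default 400 kb), separated by 350–800 bp so that every
boundary site is unambiguously nearest to its own operon. Defaults: 1–4
genes per operon; CDS lengths 200–1500 bp; 15 % of operons are
monocistronic ncRNAs of 80–300 bp; intra-operon gaps are < 15 bp half the
time (no internal UTR) and 15–200 bp otherwise; 5′/3′ UTRs of 15–300 /
15–200 bp exist with probability 0.8 each; with probability 0.25 each, an
operon gains an extra TSS or TTS (at an internal gene boundary, or as an
alternative UTR length on the first/last gene), which is what creates
isoforms and complex operons. The expected UTR counts, transcript count
(entry×exit pairs with entry not downstream of exit) and operon classes are
computed analytically from the placed sites, independent of the pipeline's
graph code, so recovery comparisons are two-route.

Three views re-express the truth: *curated* (rank 1, exact coordinates,
nucleotide-resolution sites, TU lists that randomly drop one interior gene
of larger TUs — the only dropout the method can provably recover, via TU
complementation); *homology* (rank 2, ncRNA duplicates with integer
truncated-Gaussian jitter ≤ 10 bp, keeping JI ≥ 0.5 against truth);
*tiling* (rank 3, putative-ncRNA copies and sites snapped to a 22 bp grid
with small jitter, net displacement ≤ 16 bp < the 22 bp half-width, partly
orphan-flagged). Under these tolerances the pipeline must — and in the
test suite does — recover the gene coordinates, site map, UTR counts,
transcript count and operon classes exactly. What passing these tests does
*not* show: robustness to noise beyond the stated tolerances (curated gene
dropout, site jitter past the resolution window, boundary-gene loss from
TUs), to conflicting curated coordinates, or to real-data pathologies such
as overlapping operons on one strand; expression signals are emulated only
as piecewise-constant tracks for the evidence statistics.

## Problem sizes and determinism

The default validation scale is 50 operons (~115 genes, ~120 sites) with
smaller 8–30-operon fixtures in unit tests; pairwise steps are quadratic in
local neighbourhood sizes and the whole suite runs in seconds, with ample
headroom for genome-scale inputs (thousands of genes) in minutes. All
randomness flows through explicit integer seeds into `numpy` generators —
never global state — and every stage sorts its outputs by coordinates and
identifiers, so a rerun on identical inputs is byte-identical, including
the GFF3 export (no timestamps in the body).

## Known limitations

Single replicon only; no wrap-around features. The merge step trusts the
priority ranking — a systematically wrong high-priority resource wins
systematically. Novel-TU suppression uses gene-list boundaries only, not
genomic adjacency. The ML2 statistic treats conditions as exchangeable and
has no replicate structure. GFF3 export flattens meta-value origins into a
provenance table rather than attributes.
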