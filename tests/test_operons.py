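"""Transcript graphs, path enumeration, operon components and classes."""

import pytest

from operonatlas.model import Annotation, Interval
from operonatlas.operons import (
    GuideTarget,
    Operon,
    PathExplosionError,
    Transcript,
    build_operons,
    build_transcript_graph,
    classify_operon,
    derive_tus_from_transcripts,
    enumerate_transcripts,
    expand_offtargets_by_operon,
    operon_completeness,
)
from operonatlas.sites import BoundarySite
from operonatlas.utrs import TranscriptionUnit, UTR, associate_sites_to_genes

from oracles import UnionFind, dfs_paths


def gene(gid, start, end, strand="+"):
    return Annotation(gid, Interval(start, end, strand), "CDS")


def tss(sid, pos, strand="+"):
    return BoundarySite(id=sid, position=pos, strand=strand, site_type="TSS", resource="r")


def tts(sid, pos, strand="+"):
    return BoundarySite(id=sid, position=pos, strand=strand, site_type="TTS", resource="r")


def make_tu(tid, genes, strand="+"):
    return TranscriptionUnit(
        id=tid,
        gene_ids=tuple(g.id for g in genes),
        strand=strand,
        region=Interval(min(g.interval.start for g in genes),
                        max(g.interval.end for g in genes), strand),
    )


def _enumerate(tu, genes, sites, utrs):
    genes_by_id = {g.id: g for g in genes}
    sites_by_id = {s.id: s for s in sites}
    assocs, _ = associate_sites_to_genes(sites, genes)
    graph = build_transcript_graph(tu, genes_by_id, assocs, utrs, sites_by_id)
    return graph, enumerate_transcripts(
        graph, genes_by_id, sites_by_id, {u.id: u for u in utrs}
    )


class TestTranscriptGraph:
    def test_two_gene_chain_single_path(self):
        genes = [gene("a", 100, 200), gene("b", 231, 400)]
        sites = [tss("s1", 80), tts("s2", 430)]
        utrs = [
            UTR("u5", Interval(80, 99, "+"), "five_prime", "a", source_site="s1"),
            UTR("ui", Interval(201, 230, "+"), "internal", "a", next_gene="b"),
            UTR("u3", Interval(401, 430, "+"), "three_prime", "b", source_site="s2"),
        ]
        graph, txs = _enumerate(make_tu("t", genes), genes, sites, utrs)
        assert len(txs) == 1
        (tx,) = txs
        assert tx.gene_ids == ("a", "b")
        assert [k for k, _ in tx.element_ids] == ["utr", "gene", "utr", "gene", "utr"]
        assert tx.interval == Interval(80, 430, "+")
        assert tx.is_mrna

    def test_tu_without_sites_gets_dummy_boundaries(self):
        genes = [gene("a", 100, 200), gene("b", 205, 400)]
        graph, txs = _enumerate(make_tu("t", genes), genes, [], [])
        assert {d.site_type for d in graph.dummy_sites} == {"TSS", "TTS"}
        positions = {d.site_type: d.position for d in graph.dummy_sites}
        assert positions == {"TSS": 100, "TTS": 400}  # at the terminal gene ends
        assert len(txs) == 1
        assert txs[0].gene_ids == ("a", "b")

    def test_internal_entries_and_exits_multiply_paths(self):
        """2 TSS entries x 2 TTS exits on a 3-gene chain give 4 transcripts."""
        genes = [gene("a", 100, 200), gene("b", 205, 300), gene("c", 305, 400)]
        sites = [tss("p1", 100), tss("p2", 205), tts("q1", 300), tts("q2", 400)]
        _, txs = _enumerate(make_tu("t", genes), genes, sites, [])
        gene_sets = sorted(tx.gene_ids for tx in txs)
        assert gene_sets == [("a", "b"), ("a", "b", "c"), ("b",), ("b", "c")]

    def test_tss_after_tts_yields_no_transcript(self):
        genes = [gene("a", 100, 200), gene("b", 205, 300)]
        # TSS enters at gene b, the only TTS exits at gene a: unreachable
        sites = [tss("p1", 100), tss("p2", 205), tts("q1", 200)]
        _, txs = _enumerate(make_tu("t", genes), genes, sites, [])
        assert sorted(tx.gene_ids for tx in txs) == [("a",)]

    def test_enumeration_matches_naive_dfs_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            genes = [gene(f"g{i}", 100 + 300 * i, 300 + 300 * i) for i in range(n)]
            sites = [tss("p0", 100), tts(f"q{n}", 300 + 300 * (n - 1))]
            for i in range(1, n):
                if rng.random() < 0.5:
                    sites.append(tss(f"p{i}", 100 + 300 * i))
                if rng.random() < 0.5:
                    sites.append(tts(f"qq{i}", 300 + 300 * (i - 1)))
            graph, txs = _enumerate(make_tu("t", genes), genes, sites, [])
            g = graph.graph
            oracle = dfs_paths(
                list(g.edges),
                sorted(v for v in g.nodes if v[0] == "tss"),
                [v for v in g.nodes if v[0] == "tts"],
            )
            assert sorted(
                (("tss", t.tss_id),) + t.element_ids + (("tts", t.tts_id),) for t in txs
            ) == oracle

    def test_path_cap_names_the_tu(self):
        n = 12  # 78 entry/exit pairs exceed the default cap of 64
        genes = [gene(f"g{i}", 100 + 300 * i, 300 + 300 * i) for i in range(n)]
        sites = []
        for i in range(n):
            sites.append(tss(f"p{i}", 100 + 300 * i))
            sites.append(tts(f"q{i}", 300 + 300 * i))
        tu = make_tu("crowded", genes)
        with pytest.raises(PathExplosionError, match="crowded"):
            _enumerate(tu, genes, sites, [])


class TestNovelTus:
    def _transcript(self, tid, gene_ids, tu_id, start, end):
        return Transcript(
            id=tid, tss_id=f"{tid}.s", tts_id=f"{tid}.t",
            element_ids=tuple(("gene", g) for g in gene_ids),
            gene_ids=tuple(gene_ids), tu_id=tu_id,
            interval=Interval(start, end, "+"),
        )

    def setup_method(self):
        self.genes = {g.id: g for g in [gene("g1", 100, 200), gene("g2", 300, 400),
                                        gene("g3", 500, 600)]}
        self.known = [make_tu("k1", list(self.genes.values()))]

    def test_internal_start_without_adjacent_tu_is_novel(self):
        txs = [self._transcript("t1", ["g2", "g3"], "k1", 300, 600)]
        novel = derive_tus_from_transcripts(txs, self.known, self.genes)
        assert [n.gene_ids for n in novel] == [("g2", "g3")]

    def test_known_gene_set_is_not_novel(self):
        txs = [self._transcript("t1", ["g1", "g2", "g3"], "k1", 100, 600)]
        assert derive_tus_from_transcripts(txs, self.known, self.genes) == []

    def test_adjacent_tu_starting_at_boundary_gene_suppresses(self):
        known = self.known + [make_tu("k2", [self.genes["g2"], self.genes["g3"]])]
        txs = [self._transcript("t1", ["g2", "g3"], "k1", 300, 600)]
        assert derive_tus_from_transcripts(txs, known, self.genes) == []

    def test_deduplicated_by_gene_set(self):
        txs = [
            self._transcript("t1", ["g2", "g3"], "k1", 300, 600),
            self._transcript("t2", ["g2", "g3"], "k1", 290, 620),
        ]
        assert len(derive_tus_from_transcripts(txs, self.known, self.genes)) == 1


class TestBuildOperons:
    def _tx(self, tid, gene_ids, genes_by_id):
        ivs = [genes_by_id[g].interval for g in gene_ids]
        return Transcript(
            id=tid, tss_id=f"{tid}.s", tts_id=f"{tid}.t",
            element_ids=tuple(("gene", g) for g in gene_ids),
            gene_ids=tuple(gene_ids), tu_id="tu",
            interval=Interval(min(i.start for i in ivs), max(i.end for i in ivs), "+"),
        )

    def test_shared_gene_joins_transcripts_into_one_operon(self):
        genes = {g.id: g for g in [gene("a", 1, 100), gene("b", 200, 300)]}
        txs = [self._tx("t1", ["a"], genes), self._tx("t2", ["a", "b"], genes)]
        ops = build_operons(txs, genes)
        assert len(ops) == 1 and set(ops[0].gene_ids) == {"a", "b"}

    def test_disjoint_transcripts_make_separate_operons(self):
        genes = {g.id: g for g in [gene("a", 1, 100), gene("b", 200, 300)]}
        txs = [self._tx("t1", ["a"], genes), self._tx("t2", ["b"], genes)]
        assert len(build_operons(txs, genes)) == 2

    def test_random_transcripts_match_union_find_oracle(self, rng):
        genes = {f"g{i}": gene(f"g{i}", 1 + 500 * i, 400 + 500 * i) for i in range(40)}
        txs = []
        for t in range(100):
            lo = int(rng.integers(0, 38))
            hi = lo + int(rng.integers(1, min(4, 40 - lo) + 1))
            txs.append(self._tx(f"t{t}", [f"g{i}" for i in range(lo, hi)], genes))
        ops = build_operons(txs, genes)
        uf = UnionFind([t.id for t in txs])
        gene_owner = {}
        for t in txs:
            for g in t.gene_ids:
                if g in gene_owner:
                    uf.union(t.id, gene_owner[g])
                gene_owner[g] = t.id
        oracle = UnionFind.components(uf)
        assert sorted(sorted(op.transcript_ids) for op in ops) == sorted(
            sorted(c) for c in oracle
        )

    def test_class_partition_covers_all_operons(self, rng):
        genes = {f"g{i}": gene(f"g{i}", 1 + 500 * i, 400 + 500 * i) for i in range(30)}
        txs = [
            self._tx(f"t{t}", [f"g{i}" for i in range(lo, lo + int(rng.integers(1, 4)))], genes)
            for t, lo in enumerate(rng.integers(0, 27, size=40))
        ]
        ops = build_operons(txs, genes)
        assert all(op.operon_class in ("simple", "traditional", "complex") for op in ops)
        n = {"simple": 0, "traditional": 0, "complex": 0}
        for op in ops:
            n[op.operon_class] += 1
        assert sum(n.values()) == len(ops)


class TestClassifyOperon:
    def _op(self, n_genes, n_isoforms):
        op = Operon(
            id="o", transcript_ids=tuple(f"t{i}" for i in range(max(n_isoforms, 1))),
            gene_ids=tuple(f"g{i}" for i in range(n_genes)),
            region=Interval(1, 100, "+"), operon_class="simple",
        )
        op.n_isoforms = n_isoforms
        return op

    @pytest.mark.parametrize(
        "n_genes,n_iso,expected",
        [
            (1, 1, "simple"),
            (3, 1, "traditional"),
            (1, 2, "complex"),  # monocistronic with alternative UTR lengths
            (4, 3, "complex"),
        ],
    )
    def test_class_definitions(self, n_genes, n_iso, expected):
        assert classify_operon(self._op(n_genes, n_iso)) == expected


class TestCompletenessAndGuides:
    def test_truth_pipeline_operons_are_complete(self, small_truth):
        from operonatlas.pipeline import PipelineConfig, run_pipeline
        from operonatlas.simulate import emit_resource_views

        views = emit_resource_views(small_truth)
        res = run_pipeline(
            PipelineConfig(genome_length=small_truth.genome.length),
            views=list(views.values()),
        )
        assert operon_completeness(res.atlas.operons, res.atlas.transcripts) == 1.0

    def test_offtarget_expansion(self):
        genes = {g.id: g for g in [gene("a", 100, 200), gene("b", 300, 400),
                                   gene("c", 1000, 1100)]}
        ops = [
            Operon("op1", ("t1",), ("a", "b"), Interval(100, 400, "+"), "traditional"),
            Operon("op2", ("t2",), ("c",), Interval(1000, 1100, "+"), "simple"),
        ]
        targets = [
            GuideTarget("g_in_poly", 150, "+"),
            GuideTarget("g_in_mono", 1050, "+"),
            GuideTarget("g_between", 600, "+"),
        ]
        out = expand_offtargets_by_operon(targets, ops, genes)
        by_id = {t.guide_id: t for t in out}
        assert by_id["g_in_poly"].operon_expanded_genes == {"a", "b"}
        assert by_id["g_in_mono"].operon_expanded_genes == {"c"}
        assert by_id["g_between"].operon_expanded_genes == frozenset()
        # expansion always contains the direct gene
        assert by_id["g_in_poly"].direct_gene in by_id["g_in_poly"].operon_expanded_genes
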