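"""Resource ingestion: sequence lookup, sigma-derived TSSs, name matching,
covariance-model hit filtering, and the TSV schema."""

import numpy as np
import pytest

from operonatlas.ingest import (
    AMBIGUOUS,
    NO_MATCH,
    IngestResult,
    ResourceConfig,
    RfamHit,
    SigmaSite,
    export_resource_table,
    load_resource_table,
    locate_unique_sequence,
    match_by_name,
    read_cmsearch_tblout,
    rfam_postfilter,
    tss_from_sigma_site,
)
from operonatlas.model import Annotation, GenomeRef, Interval, ModelError

from oracles import brute_name_match, brute_rfam_filter, naive_scan


class TestLocateUniqueSequence:
    def test_palindromic_single_locus_counts_once(self):
        genome = GenomeRef("g", 9, "AAACGTAAA")
        assert locate_unique_sequence(genome, "ACGT") == Interval(3, 6, "+")

    def test_two_occurrences_are_ambiguous(self):
        genome = GenomeRef("g", 8, "ACGTACGT")
        assert locate_unique_sequence(genome, "ACGT") is AMBIGUOUS

    def test_reverse_complement_only_match_reports_minus(self):
        genome = GenomeRef("g", 10, "AATTCCGGAA")
        # query GGAATT matches only as reverse complement of AATTCC at [1,6]
        assert locate_unique_sequence(genome, "GGAATT") == Interval(1, 6, "-")

    def test_absent_query_is_no_match(self):
        genome = GenomeRef("g", 8, "AAAAAAAA")
        assert locate_unique_sequence(genome, "CGCG") is NO_MATCH

    def test_non_acgt_query_rejected(self):
        genome = GenomeRef("g", 8, "AAAAAAAA")
        with pytest.raises(ModelError):
            locate_unique_sequence(genome, "ACGN")

    def test_random_18mers_found_at_source_positions(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        genome = GenomeRef("g", 5000, seq)
        for _ in range(30):
            start = int(rng.integers(0, 5000 - 18))
            query = seq[start : start + 18]
            oracle = naive_scan(seq, query)
            result = locate_unique_sequence(genome, query)
            if len(oracle) == 1:
                pos0, strand = oracle[0]
                assert result == Interval(pos0 + 1, pos0 + 18, strand)
            else:
                assert result is AMBIGUOUS


class TestSigmaSiteTss:
    @pytest.mark.parametrize(
        "iv,offset,expected_pos",
        [
            (Interval(100, 150, "+"), 10, 160),
            (Interval(100, 150, "-"), 10, 90),
            (Interval(100, 150, "+"), 0, 150),
            (Interval(100, 150, "-"), 0, 100),
        ],
    )
    def test_downstream_end_convention(self, iv, offset, expected_pos):
        site = SigmaSite(iv, "SigA", offset_to_tss=offset)
        tss = tss_from_sigma_site(site)
        assert tss.position == expected_pos
        assert tss.strand == iv.strand
        assert tss.resolution_halfwidth == 0
        assert tss.sigma_factors == frozenset({"SigA"})

    def test_start_convention_switch(self):
        site = SigmaSite(Interval(100, 150, "+"), "SigA", offset_to_tss=10)
        assert tss_from_sigma_site(site, offset_from="start").position == 110

    def test_missing_offset_is_skipped(self):
        assert tss_from_sigma_site(SigmaSite(Interval(1, 10), "SigA")) is None


class TestMatchByName:
    def _genes(self):
        return [
            Annotation("g1", Interval(1, 10), "CDS", names=frozenset({"thrS"})),
            Annotation("g2", Interval(20, 30), "CDS", names=frozenset({"yabC", "x1"})),
            Annotation("g3", Interval(40, 50), "CDS", names=frozenset({"yabC", "x2"})),
        ]

    def test_unique_and_ambiguous_and_unmatched(self):
        res = match_by_name([{"thrS"}, {"yabC"}, {"nope"}], self._genes())
        assert res[0].id == "g1"
        assert res[1] is AMBIGUOUS
        assert res[2] is NO_MATCH

    def test_matching_is_case_insensitive(self):
        res = match_by_name([{"THRS"}], self._genes())
        assert res[0].id == "g1"

    def test_hundred_genes_equal_brute_force(self, rng):
        genes = []
        for i in range(100):
            names = {f"gene{i}"}
            if rng.random() < 0.3:
                names.add(f"syn{int(rng.integers(0, 40))}")  # overlapping synonyms
            genes.append(
                Annotation(f"g{i}", Interval(1 + 10 * i, 9 + 10 * i), "CDS",
                           names=frozenset(names))
            )
        queries = [
            {f"gene{int(rng.integers(0, 120))}"} if rng.random() < 0.5
            else {f"syn{int(rng.integers(0, 40))}"}
            for _ in range(60)
        ]
        oracle = brute_name_match(queries, genes)
        got = match_by_name(queries, genes)
        for o, g in zip(oracle, got):
            if o == "unmatched":
                assert g is NO_MATCH
            elif o == "ambiguous":
                assert g is AMBIGUOUS
            else:
                assert g.id == o


def _hit(start, end, e, score=50.0, ga=30.0, strand="+", fam=None):
    return RfamHit(
        family_id=fam or f"RF_{start}_{end}",
        interval=Interval(start, end, strand),
        bit_score=score,
        e_value=e,
        gathering_score=ga,
    )


class TestRfamPostfilter:
    def test_overlapping_pair_keeps_best_e_value(self):
        hits = [_hit(100, 200, 1e-8), _hit(150, 260, 1e-7)]
        out = rfam_postfilter(hits, "medium")
        assert len(out) == 1 and out[0].e_value == 1e-8

    def test_confidence_level_cutoffs(self):
        borderline = _hit(1, 80, 1e-4)
        assert rfam_postfilter([borderline], "medium") == []
        assert rfam_postfilter([borderline], "relaxed") == [borderline]
        weak_score = _hit(1, 80, 1e-8, score=20.0, ga=30.0)
        assert rfam_postfilter([weak_score], "conservative") == []
        assert rfam_postfilter([weak_score], "medium") == [weak_score]

    def test_tie_on_e_value_breaks_by_score(self):
        hits = [_hit(1, 100, 1e-9, score=40.0), _hit(30, 130, 1e-9, score=60.0)]
        out = rfam_postfilter(hits, "medium")
        assert [h.bit_score for h in out] == [60.0]

    @pytest.mark.parametrize("level", ["conservative", "medium", "relaxed"])
    def test_random_hits_equal_brute_force_oracle(self, rng, level):
        hits = []
        for i in range(200):
            start = int(rng.integers(1, 10_000))
            hits.append(
                _hit(
                    start,
                    start + int(rng.integers(20, 300)),
                    float(10.0 ** rng.uniform(-12, -2)),
                    score=float(rng.uniform(10, 90)),
                    ga=float(rng.uniform(20, 60)),
                    strand="+" if rng.random() < 0.5 else "-",
                    fam=f"RF{i:05d}",
                )
            )
        from operonatlas.ingest import RFAM_LEVELS

        e_cut, require_ga = RFAM_LEVELS[level]
        assert rfam_postfilter(hits, level) == brute_rfam_filter(hits, e_cut, require_ga)

    def test_idempotent_and_pairwise_underlap(self, rng):
        hits = [
            _hit(int(p), int(p) + 120, 1e-8, score=float(rng.uniform(30, 80)), fam=f"R{i}")
            for i, p in enumerate(rng.integers(1, 3000, size=60))
        ]
        once = rfam_postfilter(hits, "medium")
        assert rfam_postfilter(once, "medium") == once
        assert set(once) <= set(hits)
        for i, a in enumerate(once):
            for b in once[i + 1 :]:
                if a.interval.strand == b.interval.strand:
                    assert a.interval.overlap_bp(b.interval) < 40


class TestTblout:
    def test_parse_minus_strand_and_ga(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(
            "#target name accession query ...\n"
            "genome - RF00001 - cm 1 119 2000 2118 + no 1 0.5 0.0 55.3 1.2e-09 ! desc\n"
            "genome - RF00002 - cm 1 80 3300 3221 - no 1 0.5 0.0 41.0 2.5e-05 ! desc\n"
        )
        hits = read_cmsearch_tblout(path, gathering_scores={"RF00001": 30.0})
        assert hits[0].interval == Interval(2000, 2118, "+")
        assert hits[0].gathering_score == 30.0
        assert hits[1].interval == Interval(3221, 3300, "-")
        assert hits[1].gathering_score == float("inf")


class TestResourceTable:
    def test_three_row_gene_table_stamps_resource(self, tmp_path):
        cfg = ResourceConfig("curated", 1, 2, 0, curated=True)
        path = tmp_path / "r.tsv"
        path.write_text(
            "record\tseqid\tstart\tend\tstrand\tid\tbiotype\tnames\n"
            "gene\tg\t10\t400\t+\ta\tCDS\talpha\n"
            "gene\tg\t500\t600\t-\tb\tsRNA\tbeta,b2\n"
            "gene\tg\t700\t800\t+\tc\triboswitch\t\n"
        )
        res = load_resource_table(path, cfg)
        assert len(res.annotations) == 3
        assert all(a.resource == "curated" for a in res.annotations)
        assert res.annotations[0].priority == 1  # coding rank
        assert res.annotations[1].priority == 2  # non-coding rank
        assert res.annotations[1].names == frozenset({"beta", "b2"})

    def test_tss_row_without_sigma_is_fine(self, tmp_path):
        cfg = ResourceConfig("tiling", 3, 3, 22)
        path = tmp_path / "r.tsv"
        path.write_text(
            "record\tseqid\tstart\tend\tstrand\tid\torphan\n"
            "tss\tg\t1000\t1000\t+\ts1\t1\n"
        )
        res = load_resource_table(path, cfg)
        (site,) = res.sites
        assert site.sigma_factors == frozenset()
        assert site.orphan and site.resolution_halfwidth == 22

    def test_schema_mismatch_is_descriptive(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ModelError, match="missing required columns"):
            load_resource_table(path, ResourceConfig("x"))

    def test_export_reload_round_trip(self, tmp_path, small_truth):
        from operonatlas.simulate import emit_resource_views

        views = emit_resource_views(small_truth)
        for name, view in views.items():
            path = tmp_path / f"{name}.tsv"
            export_resource_table(view, path)
            back = load_resource_table(path, view.config)
            assert back.annotations == view.annotations
            assert back.tus == view.tus
            # sites round-trip up to meta bookkeeping
            assert [
                (s.id, s.position, s.strand, s.site_type, s.orphan, s.sigma_factors)
                for s in back.sites
            ] == [
                (s.id, s.position, s.strand, s.site_type, s.orphan, s.sigma_factors)
                for s in view.sites
            ]
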