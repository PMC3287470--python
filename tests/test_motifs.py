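"""Motif compilation, scanning, sequon detection, context filtering, consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glylec.motifs import (
    AMINO_ACIDS,
    PatternError,
    TopologyAnnotation,
    TopologySegment,
    compile_motif,
    consensus_features,
    default_catalog,
    filter_by_context,
    find_sequons,
    hits_to_gff3,
    hits_to_tsv,
    read_fasta,
    read_feature_table,
    read_topology,
    scan_motifs,
)

from oracles import oracle_scan


class TestCompileMotif:
    @pytest.mark.parametrize(
        "pattern,width",
        [("[ST]xx[DE]", 4), ("[PSAT]x[QE]E", 4), ("EPN", 3), ("N{^P}[ST]", 3), ("N{P}[ST]", 3)],
    )
    def test_widths(self, pattern, width):
        assert compile_motif("m", pattern).width == width

    @pytest.mark.parametrize("bad", ["[AB", "x[", "{P", "[]", "{}", "", "N-X-S", "[ab]"])
    def test_malformed_patterns(self, bad):
        with pytest.raises(PatternError):
            compile_motif("m", bad)

    def test_negated_class_semantics(self):
        m = compile_motif("m", "{^P}")
        assert "P" not in m.positions[0] and "A" in m.positions[0]
        assert m.positions[0] == compile_motif("m", "{P}").positions[0]

    def test_catalog_contains_required_motifs(self):
        ids = {m.id for m in default_catalog()}
        assert {"EPN", "WND", "hemi-ITAM", "CKII", "TRAF2", "N-glyc-sequon"} <= ids


class TestScanMotifs:
    def test_epn_direct(self):
        (hit,) = scan_motifs("AAEPNAA", [compile_motif("EPN", "EPN")])
        assert (hit.start, hit.end, hit.matched) == (3, 5, "EPN")

    def test_ckii_window(self):
        (hit,) = scan_motifs("ASAADAA", [compile_motif("CKII", "[ST]xx[DE]")])
        assert (hit.start, hit.matched) == (2, "SAAD")

    def test_overlapping_hits_all_reported(self):
        hits = scan_motifs("YAALYAAL", [compile_motif("hemi-ITAM", "YxxL")])
        assert [h.start for h in hits] == [1, 5]

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs("ACDB*")

    def test_sorted_by_start_then_motif(self, benchmark_lectin):
        hits = scan_motifs(benchmark_lectin.sequence)
        assert hits == sorted(hits, key=lambda h: (h.start, h.motif_id))

    @settings(max_examples=150, derandomize=True)
    @given(st.text(alphabet=sorted(AMINO_ACIDS), min_size=1, max_size=80))
    def test_matches_regex_oracle(self, seq):
        catalog = default_catalog()
        hits = scan_motifs(seq, catalog)
        for motif in catalog:
            got = [(h.start, h.matched) for h in hits if h.motif_id == motif.id]
            assert got == oracle_scan(seq, motif.pattern)


class TestFindSequons:
    @pytest.mark.parametrize(
        "seq,starts",
        [("ANVSA", [2]), ("ANPSA", []), ("NNSS", [1, 2]), ("NPT", []), ("NGT", [1])],
    )
    def test_examples(self, seq, starts):
        assert [h.start for h in find_sequons(seq)] == starts

    def test_same_as_scan_with_sequon_pattern(self, benchmark_lectin):
        seq = benchmark_lectin.sequence
        a = [(h.start, h.matched) for h in find_sequons(seq)]
        b = [
            (h.start, h.matched)
            for h in scan_motifs(seq, [compile_motif("N-glyc-sequon", "N{^P}[ST]")])
        ]
        assert a == b


TOPOLOGY = TopologyAnnotation(
    (
        TopologySegment("inside", 1, 60),
        TopologySegment("transmembrane", 61, 99),
        TopologySegment("outside", 100, 378),
    )
)


class TestFilterByContext:
    def test_extracellular_sequon_kept(self):
        hits = scan_motifs("A" * 214 + "NVS" + "A" * 161)
        kept, rejected = filter_by_context(hits, TOPOLOGY)
        assert [(h.motif_id, h.start) for h in kept] == [("N-glyc-sequon", 215)]
        assert not rejected

    def test_cytoplasmic_motif_in_ectodomain_discarded(self):
        seq = "A" * 120 + "SAAD" + "A" * 254
        hits = scan_motifs(seq)
        kept, rejected = filter_by_context(hits, TOPOLOGY)
        assert not kept
        assert rejected[0].hit.start == 121 and "requires cytoplasmic" in rejected[0].rule

    def test_boundary_spanning_hit_rejected(self):
        # CKII site straddling the inside/transmembrane boundary at 60/61
        seq = "A" * 57 + "SAAD" + "A" * 317
        hits = scan_motifs(seq)
        kept, rejected = filter_by_context(hits, TOPOLOGY)
        assert not kept and rejected[0].hit.start == 58

    def test_partition_invariant(self, benchmark_lectin):
        hits = scan_motifs(benchmark_lectin.sequence)
        kept, rejected = filter_by_context(hits, benchmark_lectin.topology)
        assert len(kept) + len(rejected) == len(hits)
        assert set(kept) <= set(hits)
        assert all(r.rule for r in rejected)

    def test_hit_outside_coverage_is_an_error(self):
        hits = scan_motifs("AAEPNAA")
        short = TopologyAnnotation((TopologySegment("inside", 1, 4),))
        with pytest.raises(ValueError):
            filter_by_context(hits, short)


class TestConsensusFeatures:
    def test_two_predictor_intersection(self):
        lists = {"prosite": [16, 42, 68, 90], "elm": [16, 42, 68, 121]}
        got = consensus_features(lists, k=2)
        assert [f.start for f in got] == [16, 42, 68]
        assert all(f.predictors == ("elm", "prosite") for f in got)

    def test_k1_is_union(self):
        lists = {"a": [5, 9], "b": [9, 30]}
        assert [f.start for f in consensus_features(lists, k=1)] == [5, 9, 30]

    def test_three_way_singleton(self):
        lists = {"a": [1, 7], "b": [7, 8], "c": [7, 20]}
        got = consensus_features(lists, k=3)
        assert [(f.start, f.n_predictors) for f in got] == [(7, 3)]

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        lists = {
            f"p{i}": sorted(int(x) for x in rng.integers(1, 40, size=12)) for i in range(4)
        }
        prev = None
        for k in (1, 2, 3, 4):
            starts = {(f.feature, f.start) for f in consensus_features(lists, k=k)}
            if prev is not None:
                assert starts <= prev
            prev = starts

    def test_window_tolerance(self):
        lists = {"a": [10], "b": [11]}
        assert consensus_features(lists, k=2) == []
        assert [f.start for f in consensus_features(lists, k=2, window=1)] == [10]


class TestIO:
    def test_feature_table(self, tmp_path):
        p = tmp_path / "features.tsv"
        p.write_text(
            "predictor\tsequence_id\tfeature\tstart\tend\n"
            "prosite\tS1\tCKII\t16\t19\n"
            "elm\tS1\tCKII\t16\t19\n"
            "elm\tS1\tCKII\t42\t45\n"
        )
        tables = read_feature_table(p)
        assert set(tables) == {"prosite", "elm"}
        assert [h.start for h in tables["elm"]] == [16, 42]

    def test_feature_table_missing_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("predictor\tstart\na\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_feature_table(p)

    def test_topology_roundtrip_and_orientation(self, tmp_path):
        p = tmp_path / "topo.tsv"
        p.write_text("kind\tstart\tend\ninside\t1\t60\ntransmembrane\t61\t83\noutside\t84\t378\n")
        topo = read_topology(p)
        assert topo.length == 378 and topo.orientation == "type-II"

    def test_topology_gap_is_an_error(self, tmp_path):
        p = tmp_path / "topo.tsv"
        p.write_text("kind\tstart\tend\ninside\t1\t60\noutside\t71\t378\n")
        with pytest.raises(ValueError):
            read_topology(p)

    def test_fasta_reader_first_token_id(self, tmp_path):
        p = tmp_path / "seqs.fasta"
        p.write_text(">S1 some description\nACDEFG\n>S2\nWYYL\n")
        assert read_fasta(p) == [("S1", "ACDEFG"), ("S2", "WYYL")]

    def test_writers(self, benchmark_lectin):
        hits = scan_motifs(benchmark_lectin.sequence, sequence_id=benchmark_lectin.sequence_id)
        tsv = hits_to_tsv(hits)
        assert tsv.splitlines()[0] == "sequence_id\tmotif_id\tstart\tend\tmatched"
        assert len(tsv.strip().splitlines()) == len(hits) + 1
        gff = hits_to_gff3(hits)
        assert gff.startswith("##gff-version 3")
        assert len(gff.strip().splitlines()) == len(hits) + 1
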