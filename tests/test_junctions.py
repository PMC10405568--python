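"""Junction parsing, filtering, collapsing, classification, and RPM."""

import numpy as np
import pandas as pd
import pytest

from sisrna.annotation import IntronIndex
from sisrna.junctions import (
    INTRONIC_CIRCLE,
    STABLE_LARIAT,
    AnnotatedCall,
    JunctionCall,
    caller_overlap,
    classify_cluster,
    classify_clusters,
    collapse_junctions,
    counts_matrix,
    expressed_in_min_samples,
    filter_junctions,
    read_junction_table,
    rpm_normalize,
)

from conftest import make_intron


def ann(call, intron, concordant=True):
    return AnnotatedCall(call, intron, concordant)


class TestReader:
    def test_circexplorer2_bed_plus_strand(self, tmp_path):
        p = tmp_path / "s1.bed"
        p.write_text("chr1\t100\t600\tname\t5\t+\n")
        (call,) = read_junction_table(p, "circexplorer2_bed")
        assert (call.donor_pos, call.acceptor_pos, call.read_count) == (100, 599, 5)
        assert call.sample_id == "s1"

    def test_minus_strand_reflection(self, tmp_path):
        p = tmp_path / "s1.bed"
        p.write_text("chr1\t100\t600\tname\t5\t-\n")
        (call,) = read_junction_table(p, "circexplorer2_bed")
        assert (call.donor_pos, call.acceptor_pos) == (599, 100)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "s1.bed"
        p.write_text("chr1\t600\t100\tname\t5\t+\nchr1\t100\t600\tn\t2\t+\n")
        calls = read_junction_table(p, "circexplorer2_bed")
        assert len(calls) == 1

    def test_generic_tsv_with_header(self, tmp_path):
        p = tmp_path / "s2.tsv"
        p.write_text("chrom\tstart\tend\tstrand\tread_count\nchr2\t10\t110\t+\t3\n")
        (call,) = read_junction_table(p, "generic_tsv")
        assert (call.chrom, call.donor_pos, call.acceptor_pos, call.read_count) == (
            "chr2", 10, 109, 3,
        )


class TestFilters:
    @pytest.fixture
    def setup(self):
        introns = [
            make_intron("pc1", start=1000, end=2000, gene_id="coding"),
            make_intron("nc1", start=5000, end=6000, gene_id="linc"),
            make_intron("mt1", chrom="chrM", start=100, end=900, gene_id="mito"),
        ]
        biotypes = {"coding": "protein_coding", "linc": "lincRNA",
                    "mito": "protein_coding"}
        return IntronIndex(introns), biotypes

    def test_filter_categories_and_conservation(self, setup):
        index, biotypes = setup
        calls = [
            JunctionCall("s", "chrM", "+", 150, 400, 2),       # mitochondrial
            JunctionCall("s", "chr1", "+", 1000, 1024, 2),     # length 25 < 30
            JunctionCall("s", "chr1", "+", 5000, 5500, 2),     # ncRNA host
            JunctionCall("s", "chr9", "+", 10, 400, 2),        # no host intron
            JunctionCall("s", "chr1", "+", 1000, 1500, 2),     # kept
        ]
        kept, fc = filter_junctions(calls, index, biotypes)
        assert fc.input == 5 and fc.kept == 1
        assert (fc.removed_mito, fc.removed_length, fc.removed_biotype,
                fc.removed_no_host) == (1, 1, 1, 1)
        assert fc.input == fc.kept + fc.removed_mito + fc.removed_length \
            + fc.removed_biotype + fc.removed_no_host
        assert kept[0].intron.intron_id == "pc1"

    @pytest.mark.parametrize("length,kept", [(29, 0), (30, 1), (10_000, 0)])
    def test_length_boundaries(self, setup, length, kept):
        # 10 000 exceeds the host intron span here, so it has no host
        index, biotypes = setup
        calls = [JunctionCall("s", "chr1", "+", 1000, 1000 + length - 1, 2)]
        got, _ = filter_junctions(calls, index, biotypes)
        assert len(got) == kept


class TestCollapse:
    @pytest.fixture
    def intron(self):
        return make_intron("host", start=900, end=2100, gene_id="g")

    def test_representative_is_max_read_member(self, intron):
        calls = [
            JunctionCall("s1", "chr1", "+", 1000, 2000, 5),
            JunctionCall("s1", "chr1", "+", 1000, 1998, 2),
            JunctionCall("s2", "chr1", "+", 1000, 1995, 1),
        ]
        (cluster,) = collapse_junctions([ann(c, intron) for c in calls])
        assert cluster.representative_end == 2000
        assert cluster.total_reads == 8
        assert cluster.n_samples_expressed == 2

    def test_reads_conserved_across_members(self, intron, rng):
        calls = []
        total = 0
        for i in range(40):
            n = int(rng.integers(1, 9))
            total += n
            calls.append(
                JunctionCall(f"s{i % 5}", "chr1", "+", 1000,
                             int(rng.integers(1500, 2050)), n)
            )
        (cluster,) = collapse_junctions([ann(c, intron) for c in calls])
        assert cluster.total_reads == total
        assert sum(m.reads for m in cluster.members) == total

    def test_distinct_donors_make_distinct_clusters(self, intron):
        calls = [
            JunctionCall("s1", "chr1", "+", 1000, 2000, 3),
            JunctionCall("s1", "chr1", "+", 1100, 2000, 3),
        ]
        clusters = collapse_junctions([ann(c, intron) for c in calls])
        assert len(clusters) == 2

    def test_tie_break_chain(self, intron):
        # 5 vs 5 reads: member seen in more samples wins
        calls = [
            JunctionCall("s1", "chr1", "+", 1000, 1990, 5),
            JunctionCall("s1", "chr1", "+", 1000, 1980, 3),
            JunctionCall("s2", "chr1", "+", 1000, 1980, 2),
        ]
        (c,) = collapse_junctions([ann(x, intron) for x in calls])
        assert c.representative_end == 1980
        # equal reads and samples: smaller |end - 3'SS| wins (3'SS = 2099)
        calls = [
            JunctionCall("s1", "chr1", "+", 1000, 1990, 5),
            JunctionCall("s1", "chr1", "+", 1000, 2080, 5),
        ]
        (c,) = collapse_junctions([ann(x, intron) for x in calls])
        assert c.representative_end == 2080

    def test_zero_read_calls_dropped(self, intron):
        calls = [
            JunctionCall("s1", "chr1", "+", 1000, 2000, 0),
            JunctionCall("s2", "chr1", "+", 1000, 2000, 4),
        ]
        (c,) = collapse_junctions([ann(x, intron) for x in calls])
        assert c.n_samples_expressed == 1 and c.total_reads == 4

    def test_order_invariance(self, intron, rng):
        calls = [
            JunctionCall(f"s{i % 7}", "chr1", "+",
                         1000 + 10 * int(rng.integers(0, 3)),
                         int(rng.integers(1500, 2050)), int(rng.integers(1, 6)))
            for i in range(60)
        ]
        ref = collapse_junctions([ann(c, intron) for c in calls])
        for _ in range(5):
            shuffled = list(calls)
            rng.shuffle(shuffled)
            got = collapse_junctions([ann(c, intron) for c in shuffled])
            assert [(c.cluster_id, c.representative_end, c.total_reads) for c in got] \
                == [(c.cluster_id, c.representative_end, c.total_reads) for c in ref]


class TestClassification:
    def _cluster(self, intron, end):
        calls = [JunctionCall("s1", intron.chrom, intron.strand,
                              intron.five_prime_pos, end, 5)]
        (c,) = collapse_junctions([ann(x, intron) for x in calls])
        return c

    def test_end_at_last_base_is_circle(self):
        intron = make_intron("i", start=1000, end=2000)
        c = self._cluster(intron, 1999)
        assert classify_cluster(c) == INTRONIC_CIRCLE

    def test_interior_end_is_lariat(self):
        intron = make_intron("i", start=1000, end=2000)
        c = self._cluster(intron, 1969)
        assert classify_cluster(c) == STABLE_LARIAT

    def test_tolerance_semantics(self):
        intron = make_intron("i", start=1000, end=2000)
        c = self._cluster(intron, 1998)
        assert classify_cluster(c, tol_3ss=0) == STABLE_LARIAT
        assert classify_cluster(c, tol_3ss=1) == INTRONIC_CIRCLE

    def test_minus_strand_3ss_is_span_start(self):
        intron = make_intron("i", strand="-", start=1000, end=2000)
        c = self._cluster(intron, 1000)
        assert classify_cluster(c) == INTRONIC_CIRCLE

    def test_end_outside_intron_excluded_with_report(self):
        intron = make_intron("i", start=1000, end=2000)
        c = self._cluster(intron, 1500)
        object.__setattr__(c, "representative_end", 2500)
        ok, excluded = classify_clusters([c])
        assert ok == [] and len(excluded) == 1

    def test_min_samples_rule(self):
        intron = make_intron("i", start=1000, end=2000)
        calls = [
            JunctionCall("s1", "chr1", "+", 1000, 1500, 1),
            JunctionCall("s2", "chr1", "+", 1000, 1500, 1),
            JunctionCall("s1", "chr1", "+", 1100, 1500, 9),
        ]
        clusters = collapse_junctions([ann(c, intron) for c in calls])
        kept = expressed_in_min_samples(clusters, 2)
        assert len(kept) == 1 and kept[0].donor_pos == 1000


class TestRPM:
    def test_values_and_invariance(self):
        counts = pd.DataFrame({"s1": [2, 0]}, index=["a", "b"])
        rpm = rpm_normalize(counts, {"s1": 1_000_000})
        assert rpm.loc["a", "s1"] == 2.0 and rpm.loc["b", "s1"] == 0.0
        doubled = rpm_normalize(counts * 2, {"s1": 2_000_000})
        pd.testing.assert_frame_equal(rpm, doubled)

    def test_missing_library_size_names_sample(self):
        counts = pd.DataFrame({"s9": [1]}, index=["a"])
        with pytest.raises(KeyError, match="s9"):
            rpm_normalize(counts, {})


class TestCallerOverlap:
    def test_identical_and_disjoint(self):
        a = [("chr1", "+", 100, 500), ("chr2", "-", 50, 400)]
        res = caller_overlap({"c1": a, "c2": list(a)}, tol=0)
        assert res.overall == 1.0
        b = [("chr3", "+", 100, 500)]
        res = caller_overlap({"c1": a, "c2": b}, tol=0)
        assert res.overall == 0.0

    def test_jittered_matches_brute_force(self, rng):
        keys = [
            ("chr1", "+", int(d), int(e))
            for d, e in zip(rng.integers(0, 10_000, 80), rng.integers(0, 10_000, 80))
        ]
        jittered = [
            (c, s, d + int(rng.integers(-3, 4)), e + int(rng.integers(-3, 4)))
            for c, s, d, e in keys
        ]
        tol = 3
        res = caller_overlap({"a": keys, "b": jittered}, tol=tol)

        def brute(frm, to):
            n = 0
            for c, s, d, e in frm:
                if any(
                    c == c2 and s == s2 and abs(d - d2) <= tol and abs(e - e2) <= tol
                    for c2, s2, d2, e2 in to
                ):
                    n += 1
            return n / len(frm)

        assert res.per_caller["a"] == pytest.approx(brute(keys, jittered))
        assert res.per_caller["b"] == pytest.approx(brute(jittered, keys))
        assert res.per_caller["a"] == 1.0  # every jittered end is within tol


def test_counts_matrix_columns_and_sums():
    intron = make_intron("i", start=1000, end=2000)
    calls = [
        JunctionCall("s1", "chr1", "+", 1000, 1500, 3),
        JunctionCall("s2", "chr1", "+", 1000, 1400, 2),
    ]
    clusters = collapse_junctions([ann(c, intron) for c in calls])
    m = counts_matrix(clusters, ["s1", "s2", "s3"])
    assert list(m.columns) == ["s1", "s2", "s3"]
    assert m.loc["i:1000"].tolist() == [3, 2, 0]
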