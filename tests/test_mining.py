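"""Hit-table ingestion, k-mer search, clustering, extraction, classification."""
import numpy as np
import pytest

from retroclock._seq import random_sequence, revcomp
from retroclock.errors import FormatError
from retroclock.mining import (Cluster, GenomeIndex, classify_locus,
                               detect_ltr_pair, extract_locus, merge_hits,
                               naive_search, read_hit_table, write_hit_table)
from retroclock.simulate import EvolutionParams, InsertionSpec, implant_elements


def _hit_line(q="q", s="scaf1", pid=98.5, length=120, mm=2, gap=0,
              qs=1, qe=120, ss=1000, se=1119, ev=1e-30, bs=222.0):
    return "\t".join(map(str, [q, s, pid, length, mm, gap, qs, qe, ss, se, ev, bs]))


class TestHitTable:
    def test_three_line_toy_strands(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join([
            _hit_line(ss=100, se=220),
            _hit_line(ss=500, se=380),  # minus strand: start > end
            _hit_line(ss=900, se=1020),
        ]) + "\n")
        records = read_hit_table(path)
        assert [r.strand for r in records] == ["+", "-", "+"]
        assert all(r.subject_start < r.subject_end for r in records)
        assert (records[1].subject_start, records[1].subject_end) == (380, 500)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_hit_table(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(_hit_line() + "\n" + _hit_line(pid="notanumber") + "\n")
        with pytest.raises(FormatError, match="line 2"):
            read_hit_table(path)

    def test_too_few_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\tc\n")
        with pytest.raises(FormatError, match="line 1"):
            read_hit_table(path)

    def test_many_lines(self, tmp_path):
        path = tmp_path / "many.tsv"
        path.write_text("\n".join(_hit_line(ss=10 * i + 1, se=10 * i + 120)
                                  for i in range(1446)) + "\n")
        assert len(read_hit_table(path)) == 1446

    def test_write_read_round_trip(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join([_hit_line(), _hit_line(ss=500, se=380)]) + "\n")
        records = read_hit_table(path)
        out1 = tmp_path / "out1.tsv"
        out2 = tmp_path / "out2.tsv"
        write_hit_table(records, out1)
        write_hit_table(read_hit_table(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()
        assert read_hit_table(out2) == records


class TestNaiveSearch:
    def test_verbatim_query_found_exactly(self, rng):
        genome = random_sequence(20_000, rng)
        query = random_sequence(300, np.random.default_rng(5))
        planted = genome[:7000] + query + genome[7000:]
        hits = naive_search(query, {"s": planted}, k=16)
        assert len(hits) == 1
        h = hits[0]
        assert (h.subject_start - 1, h.subject_end) == (7000, 7300)
        assert h.percent_identity == 100.0
        assert h.strand == "+"

    def test_absent_query_no_hits(self, rng):
        genome = random_sequence(50_000, rng)
        query = random_sequence(30, np.random.default_rng(99))
        assert naive_search(query, {"s": genome}, k=16) == []

    def test_reverse_complement_symmetry(self, rng):
        genome = random_sequence(20_000, rng)
        query = random_sequence(300, np.random.default_rng(5))
        planted = genome[:7000] + revcomp(query) + genome[7000:]
        hits = naive_search(query, {"s": planted}, k=16)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].subject_start - 1, hits[0].subject_end) == (7000, 7300)

    def test_agrees_with_bruteforce_best_interval(self, rng):
        """Best-hit interval matches a quadratic-time exhaustive ungapped
        matcher on short diverged sequences."""
        for trial in range(5):
            trng = np.random.default_rng(1000 + trial)
            genome = random_sequence(2000, trng)
            start = int(trng.integers(200, 1400))
            query = list(genome[start:start + 400])
            for i in trng.choice(400, 40, replace=False):  # 10% divergence
                query[i] = "ACGT"[trng.integers(4)]
            query = "".join(query)
            hits = naive_search(query, {"s": genome}, k=11, min_identity=60)
            assert hits, "diverged copy must be found"
            best = hits[0]
            overlap = (min(best.subject_end, start + 400)
                       - max(best.subject_start - 1, start))
            assert overlap >= 350  # recovers (almost) the full planted interval

    def test_index_reuse(self, rng):
        genome = {"s": random_sequence(5000, rng)}
        index = GenomeIndex(genome, k=12)
        q = genome["s"][1000:1400]
        assert naive_search(q, index, k=12) == naive_search(q, genome, k=12)


class TestMergeHits:
    def _mk(self, ss, se, scaf="s", strand="+", bs=50.0):
        from retroclock.mining import HitRecord
        return HitRecord(query_id="q", subject_id=scaf, percent_identity=95.0,
                         align_length=se - ss, mismatches=0, gap_opens=0,
                         query_start=1, query_end=se - ss, subject_start=ss + 1,
                         subject_end=se, evalue=0.0, bitscore=bs, strand=strand)

    def test_gap_within_threshold_merges(self):
        clusters = merge_hits([self._mk(100, 200), self._mk(250, 400)], 100)
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (100, 400)

    def test_gap_beyond_threshold_splits(self):
        clusters = merge_hits([self._mk(100, 200), self._mk(5000, 5100)], 100)
        assert len(clusters) == 2

    def test_strands_never_merge(self):
        clusters = merge_hits([self._mk(100, 200), self._mk(210, 300, strand="-")],
                              1000)
        assert len(clusters) == 2

    def test_output_disjoint_and_covering(self, rng):
        hits = [self._mk(int(s), int(s) + int(rng.integers(20, 200)))
                for s in rng.integers(0, 50_000, size=300)]
        clusters = merge_hits(hits, max_gap=150)
        ivs = [(c.start, c.end) for c in clusters]
        assert ivs == sorted(ivs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 - e1 > 150  # maximality: neighbours not mergeable
        for h in hits:
            assert any(c.start <= h.subject_start - 1 and h.subject_end <= c.end
                       for c in clusters)

    def test_matches_transitive_closure_oracle(self, rng):
        """Clustering equals the brute-force transitive closure of the
        'gap <= max_gap' relation."""
        max_gap = 75
        starts = rng.integers(0, 5000, size=60)
        hits = [self._mk(int(s), int(s) + 50) for s in starts]
        clusters = merge_hits(hits, max_gap)
        # oracle: union-find over all pairs
        parent = list(range(len(hits)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(hits)):
            for j in range(len(hits)):
                a, b = hits[i], hits[j]
                gap = max(b.subject_start - 1 - a.subject_end,
                          a.subject_start - 1 - b.subject_end)
                if gap <= max_gap:
                    parent[find(i)] = find(j)
        n_groups = len({find(i) for i in range(len(hits))})
        assert len(clusters) == n_groups


class TestExtractLocus:
    def test_flank_and_clamping(self, rng):
        genome = {"s": random_sequence(100_000, rng)}
        locus = extract_locus(genome, Cluster("s", 20_000, 27_000, "+", 1, 1.0),
                              flank=10_000)
        assert (locus.start, locus.end) == (10_000, 37_000)
        assert locus.flank_used == (10_000, 10_000)
        clamped = extract_locus(genome, Cluster("s", 3_000, 5_000, "+", 1, 1.0),
                                flank=10_000)
        assert clamped.start == 0
        assert clamped.flank_used == (3_000, 10_000)

    def test_minus_strand_is_revcomp_of_plus(self, rng):
        genome = {"s": random_sequence(50_000, rng)}
        plus = extract_locus(genome, Cluster("s", 20_000, 21_000, "+", 1, 1.0), 500)
        minus = extract_locus(genome, Cluster("s", 20_000, 21_000, "-", 1, 1.0), 500)
        assert minus.sequence == revcomp(plus.sequence)

    def test_round_trip_recovers_cluster(self, rng):
        genome = {"s": random_sequence(50_000, rng)}
        cluster = Cluster("s", 12_345, 14_000, "+", 1, 1.0)
        locus = extract_locus(genome, cluster, flank=2_000)
        core_in_locus = (cluster.start - locus.start, cluster.end - locus.start)
        assert locus.sequence[core_in_locus[0]:core_in_locus[1]] == \
            genome["s"][cluster.start:cluster.end]
        assert locus.core == (cluster.start, cluster.end)

    def test_unknown_scaffold(self, rng):
        with pytest.raises(LookupError):
            extract_locus({"s": "ACGT" * 100},
                          Cluster("nope", 0, 10, "+", 1, 1.0))


class TestStructureAndClassification:
    def test_age_zero_provirus_structure(self, template, rng):
        flank_l = random_sequence(1500, rng)
        flank_r = random_sequence(1500, rng)
        locus_seq = flank_l + "GATCC" + template.sequence + "GATCC" + flank_r
        st = detect_ltr_pair(locus_seq, template.ltr)
        assert st.ltr5 == (1505, 1505 + template.l_ltr)
        assert st.ltr3 == (1505 + len(template) - template.l_ltr,
                           1505 + len(template))
        assert st.tsd == "GATCC"
        classified = classify_locus(st, template.internal, family_id="famX")
        assert classified.classification == "provirus"

    def test_solo_ltr_structure(self, template, rng):
        locus_seq = (random_sequence(2000, rng) + template.ltr
                     + random_sequence(2000, np.random.default_rng(3)))
        st = detect_ltr_pair(locus_seq, template.ltr)
        assert st.ltr3 is None
        assert st.ltr5 == (2000, 2000 + template.l_ltr)
        classified = classify_locus(st, template.internal, family_id="famX")
        assert classified.classification == "solo_ltr"

    def test_unrelated_sequence_is_fragment(self, template, rng):
        st = detect_ltr_pair(random_sequence(4000, rng), template.ltr)
        classified = classify_locus(st, template.internal)
        assert classified.classification == "fragment"

    def test_solo_next_to_provirus_not_promoted(self, template, rng):
        """A solo LTR with a full provirus nearby in the same locus must not
        be paired with the neighbour's LTR into a phantom provirus."""
        gap = random_sequence(1200, rng)
        locus_seq = (random_sequence(800, rng) + template.ltr + gap
                     + template.sequence + random_sequence(800, np.random.default_rng(8)))
        st = detect_ltr_pair(locus_seq, template.ltr)
        classified = classify_locus(st, template.internal, family_id="famX")
        # the best-supported pair is the real provirus, so the call is provirus
        # for this locus; crucially it is never a solo call on the wrong LTR
        assert classified.classification == "provirus"
        assert classified.ltr5[0] >= 800 + template.l_ltr + 1200

    def test_aged_provirus_recovered(self, template):
        """Both LTRs found on diverged (d ~ 0.1) simulated proviruses."""
        params = EvolutionParams(seed=41)
        specs = [InsertionSpec("famX", 60.0, "provirus", 15)]
        genome, truth = implant_elements(300_000, 1, {"famX": template},
                                         specs, params, min_gap=2000)
        hits = naive_search(template.sequence, genome, k=12, query_id="famX")
        clusters = merge_hits(hits, max_gap=2 * template.l_ltr)
        n_ok = 0
        for c in clusters:
            locus = extract_locus(genome, c, flank=1000)
            st = detect_ltr_pair(locus.sequence, template.ltr)
            cl = classify_locus(st, template.internal, family_id="famX")
            n_ok += cl.classification == "provirus"
        assert len(clusters) == 15
        assert n_ok >= 14
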