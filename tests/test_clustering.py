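"""Cluster assembly, chimera detection and intra-amplicon typology."""
import numpy as np

from amplicall.clustering import (
    classify_amplicon,
    classify_intra,
    cluster_reads,
    detect_chimera,
    edit_distance,
)
from amplicall.types import IntraLabel, SequenceRead


def _reads(seq_counts):
    reads, i = [], 0
    for seq, n in seq_counts.items():
        for _ in range(n):
            i += 1
            reads.append(SequenceRead(f"r{i}", seq, None))
    return reads


def brute_force_is_chimera(query, parents):
    """Independent oracle: try every ordered parent pair and every splice
    point by explicit string construction."""
    lq = len(query)
    for r1, s1 in parents:
        for r2, s2 in parents:
            if r1 == r2:
                continue
            for i in range(1, min(len(s1), lq - 1) + 1):
                j = len(s2) - (lq - i)
                if j < 1 or j > len(s2):
                    continue
                product = s1[:i] + s2[j:]
                if product == query and query != s1 and query != s2:
                    return True
    return False


class TestClusterReads:
    def test_ranked_clusters_and_singletons(self):
        reads = _reads({"AAAA": 3, "CCCC": 2, "GGGG": 1, "TTTT": 1})
        clusters, singles = cluster_reads("amp", reads)
        assert [(c.sequence, c.count, c.rank) for c in clusters] == [
            ("AAAA", 3, 1),
            ("CCCC", 2, 2),
        ]
        assert [c.frequency for c in clusters] == [0.6, 0.4]
        assert sorted(s.sequence for s in singles) == ["GGGG", "TTTT"]

    def test_all_identical(self):
        clusters, singles = cluster_reads("amp", _reads({"ACGT": 10}))
        assert len(clusters) == 1 and clusters[0].frequency == 1.0
        assert singles == []

    def test_tie_break_lexicographic(self):
        clusters, _ = cluster_reads("amp", _reads({"TTTT": 2, "AAAA": 2}))
        assert [c.sequence for c in clusters] == ["AAAA", "TTTT"]

    def test_conservation(self):
        counts = {"A" * 8: 5, "C" * 8: 3, "G" * 8: 1, "T" * 8: 2, "AC" * 4: 1}
        reads = _reads(counts)
        clusters, singles = cluster_reads("amp", reads)
        assert sum(c.count for c in clusters) + len(singles) == len(reads)

    def test_empty(self):
        assert cluster_reads("amp", []) == ([], [])


class TestDetectChimera:
    def test_constructed_splice_found(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=60))
        p1 = list(base)
        p2 = list(base)
        p1[10], p2[10] = "A", "C"
        p1[50], p2[50] = "G", "T"
        p1, p2 = "".join(p1), "".join(p2)
        query = p1[:30] + p2[30:]
        cert = detect_chimera(query, [(1, p1), (2, p2)])
        assert cert is not None
        r1, r2, b = cert
        assert (r1, r2) == (1, 2) and 10 < b <= 50
        assert p1[:b] + p2[b:] == query

    def test_query_equal_to_parent_is_not_chimera(self):
        p1, p2 = "AAAATTTT", "AAAACCCC"
        assert detect_chimera(p1, [(1, p1), (2, p2)]) is None

    def test_no_decomposition(self):
        p1, p2 = "AAAAAAAA", "CCCCCCCC"
        query = "GGGGGGGG"
        assert detect_chimera(query, [(1, p1), (2, p2)]) is None

    def test_matches_oracle_on_random_instances(self, rng):
        """Detector verdicts equal exhaustive splice enumeration."""
        n_instances, length = 200, 40
        for _ in range(n_instances):
            base = "".join(rng.choice(list("ACGT"), size=length))
            n_parents = int(rng.integers(2, 6))
            parents = []
            for r in range(n_parents):
                seq = list(base)
                for pos in rng.choice(length, size=int(rng.integers(1, 5)),
                                      replace=False):
                    seq[pos] = str(rng.choice(list("ACGT")))
                parents.append((r + 1, "".join(seq)))
            if rng.random() < 0.5:
                i, j = rng.choice(n_parents, size=2, replace=False)
                b = int(rng.integers(1, length))
                query = parents[i][1][:b] + parents[j][1][b:]
            else:
                query = list(base)
                for pos in rng.choice(length, size=3, replace=False):
                    query[pos] = str(rng.choice(list("ACGT")))
                query = "".join(query)
            expected = brute_force_is_chimera(query, parents)
            got = detect_chimera(query, parents)
            assert (got is not None) == expected
            if got is not None:
                r1, r2, b = got
                seqs = dict(parents)
                assert seqs[r1][:b] + seqs[r2][b:] == query  # equal lengths here

    def test_unequal_length_parents(self):
        # a 3-bp deletion variant can still act as splice partner
        p1 = "AAAACCCCGGGGTTTT"
        p2 = "AAAACCGGGGTTTT" + "CA"  # same length not required of p2's tail
        query = p1[:6] + p2[4:]
        if query not in (p1, p2):
            cert = detect_chimera(query, [(1, p1), (2, p2)])
            assert cert is not None


class TestClassifyIntra:
    def test_substitution_distances(self):
        top = "AAAAAAAAAA"
        one_off = "AAAAAAAAAC"
        far = "CCCCCGGGGG"
        clusters, _ = cluster_reads(
            "amp", _reads({top: 10, one_off: 3, far: 2})
        )
        classify_intra(clusters)
        by_seq = {c.sequence: c for c in clusters}
        assert by_seq[top].intra_label is IntraLabel.TOP
        assert by_seq[one_off].intra_label is IntraLabel.DIFF_1_2
        assert by_seq[far].intra_label is IntraLabel.DIFF_GT2
        assert by_seq[one_off].nearest_parent == (1, 1)

    def test_chimera_precedence_over_distance(self, rng):
        # a variant both 1 bp from a parent and decomposable as a splice is
        # labelled chimera: the splice test runs first
        p1 = "AAAAAAAAGG"
        p2 = "AAAAAAAACC"
        query = "AAAAAAAAGC"  # p1[:9] + p2[9:], also 1 bp from both
        clusters, _ = cluster_reads("amp", _reads({p1: 10, p2: 8, query: 3}))
        classify_intra(clusters)
        q = next(c for c in clusters if c.sequence == query)
        assert q.intra_label is IntraLabel.CHIMERA

    def test_parents_must_be_strictly_more_frequent(self):
        # equal-count clusters cannot source each other
        a = "AAAAAAAAAA"
        b = "AAAAAAAACC"  # 2 bp from a, same count
        clusters, _ = cluster_reads("amp", _reads({a: 5, b: 5}))
        classify_intra(clusters)
        by_seq = {c.sequence: c for c in clusters}
        assert by_seq[a].intra_label is IntraLabel.TOP
        # b is ranked 2 by tie-break but has no strictly-more-frequent
        # parent; it still gets a distance label from the higher rank
        assert by_seq[b].intra_label is IntraLabel.DIFF_1_2

    def test_codon_indel_distance_counts_gap_columns(self):
        assert edit_distance("GCTGCAGCT", "GCTGCT") == 3

    def test_simulated_amplicon_truth_labels(self):
        """Planted artefact taxonomy recovered label-for-label."""
        from amplicall.simulate import preset_config, simulate_amplicon

        config = preset_config(
            "paper-like",
            singleton_rate=0.0,
            frameshift_read_fraction=0.0,
            low_quality_read_fraction=0.0,
        )
        rng = np.random.default_rng(7)
        seqs = {
            "A1": "GCTGCAGCT" * 8,
            "A2": ("GCA" * 4 + "GCT" * 4) * 3,
            "A3": ("TCT" * 8 + "GGA" * 8) + "GCT" * 8,
        }
        items, _ = simulate_amplicon(
            ["A1", "A2", "A3"], seqs, {"A1": 1.0, "A2": 0.8, "A3": 0.5},
            600, config, rng,
        )
        reads = [SequenceRead(f"r{i}", s, None) for i, (s, _, _) in enumerate(items)]
        truth_kind = {}
        for s, kind, _ in items:
            truth_kind[s] = kind
        clusters, _ = cluster_reads("amp", reads)
        classify_intra(clusters)
        for c in clusters:
            kind = truth_kind[c.sequence]
            if kind == "allele":
                continue
            if kind == "chimera":
                assert c.intra_label is IntraLabel.CHIMERA
            elif kind == "early_error":
                assert c.intra_label in (IntraLabel.DIFF_1_2, IntraLabel.CHIMERA)
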