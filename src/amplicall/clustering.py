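"""Intra-amplicon variant clustering and artefact typology.

Within one amplicon, identical reads are collapsed into clusters ranked by
abundance.  Sequences seen only once (singletons) are set aside as putative
artefacts: the chance that the same polymerase or sequencing error occurs
independently in two reads is negligible, so a one-read sequence carries no
evidence of being real.  Every remaining cluster below rank 1 then receives
an intra-amplicon category:

``CHIMERA``
    the sequence can be spliced from two distinct strictly-more-frequent
    clusters at a single breakpoint (PCR template switching produces such
    hybrids, always at lower abundance than both source molecules);
``DIFF_1_2``
    one or two base differences from the most similar strictly-more-frequent
    cluster (typical of amplified polymerase misincorporations);
``DIFF_GT2``
    more than two base differences (complex artefacts: mosaics of more than
    two fragments, chimeras carrying additional errors — or real alleles).

The chimera test is applied first; a cluster that is both one base from a
parent and chimeric is labelled ``CHIMERA``.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from typing import Optional, Sequence

import edlib

from .types import IntraLabel, SequenceRead, SingletonRecord, VariantCluster


def cluster_reads(
    amplicon_id: str, reads: Sequence[SequenceRead]
) -> tuple[list[VariantCluster], list[SingletonRecord]]:
    """Collapse identical reads into ranked clusters; isolate singletons.

    Clusters are sorted by count descending with lexicographic tie-break on
    the sequence, so ranking is deterministic.  Frequencies are computed
    over non-singleton reads only.
    """
    counts = Counter(r.bases for r in reads)
    first_read_id: dict[str, str] = {}
    for r in reads:
        first_read_id.setdefault(r.bases, r.read_id)

    singletons = [
        SingletonRecord(amplicon_id, seq, first_read_id[seq])
        for seq, n in counts.items()
        if n == 1
    ]
    singletons.sort(key=lambda s: s.sequence)

    multi = [(seq, n) for seq, n in counts.items() if n >= 2]
    multi.sort(key=lambda item: (-item[1], item[0]))
    total = sum(n for _, n in multi)
    clusters = [
        VariantCluster(
            amplicon_id=amplicon_id,
            sequence=seq,
            count=n,
            rank=i + 1,
            frequency=n / total,
        )
        for i, (seq, n) in enumerate(multi)
    ]
    return clusters, singletons


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def detect_chimera(
    query: str, parents: Sequence[tuple[int, str]]
) -> Optional[tuple[int, int, int]]:
    """Test whether ``query`` is a single-breakpoint splice of two parents.

    ``parents`` are (rank, sequence) pairs of clusters with strictly higher
    count in the same amplicon.  Returns a certificate
    ``(rank_left, rank_right, breakpoint)`` such that
    ``query == left[:b'] + right[j:]`` with the breakpoint measured on the
    query (``b'`` query positions from the left parent, the remainder from
    the right), or ``None``.  The query must differ from both parents, and
    the two parents must be distinct clusters.  Among multiple certificates
    the lexicographically smallest (rank_left, rank_right, breakpoint) is
    returned.

    Implementation: for each parent, the longest common prefix and suffix
    with the query are precomputed; a pair admits a splice iff their valid
    breakpoint intervals overlap.  Parents of a different length than the
    query are handled by letting the splice consume unequal amounts of each
    parent (a single-breakpoint alignment-aware join).
    """
    lq = len(query)
    ordered = sorted(parents, key=lambda p: p[0])
    pre = {rank: _lcp(seq, query) for rank, seq in ordered}
    suf = {rank: _lcs(seq, query) for rank, seq in ordered}
    for rank1, seq1 in ordered:
        if seq1 == query:
            continue
        hi = min(pre[rank1], len(seq1), lq - 1)
        if hi < 1:
            continue
        for rank2, seq2 in ordered:
            if rank2 == rank1 or seq2 == query:
                continue
            # splice query[:b] from seq1 and query[b:] from seq2; the suffix
            # taken from seq2 must leave at least 1 base of seq2 unused on
            # the left and contribute at least 1 base.
            lo = max(1, lq - suf[rank2], lq - len(seq2) + 1)
            if lo <= hi:
                return (rank1, rank2, lo)
    return None


def edit_distance(a: str, b: str) -> int:
    """Global pairwise distance: mismatches plus gap columns, each one unit.

    A global (end-to-end) alignment is used so that codon-length indel
    variants, which pass the length filter, remain comparable.
    """
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def classify_intra(clusters: Sequence[VariantCluster]) -> None:
    """Assign intra-amplicon labels in place to a ranked cluster list.

    Rank 1 is ``TOP``.  Every other cluster is first tested as a chimera of
    strictly-more-frequent clusters; failing that, it is labelled by its
    distance to the most similar strictly-more-frequent cluster (ties on
    distance broken by lowest rank).
    """
    for cluster in clusters:
        if cluster.rank == 1:
            cluster.intra_label = IntraLabel.TOP
            continue
        parents = [
            (c.rank, c.sequence) for c in clusters if c.count > cluster.count
        ]
        if parents:
            cert = detect_chimera(cluster.sequence, parents)
            if cert is not None:
                cluster.intra_label = IntraLabel.CHIMERA
                cluster.chimera_parents = cert
                continue
        if not parents:
            # equal-count ties with rank 1: no strictly-more-frequent
            # comparator exists; fall back to the higher-ranked clusters so
            # the variant still receives a distance-based label.
            parents = [
                (c.rank, c.sequence)
                for c in clusters
                if c.rank < cluster.rank
            ]
        best: Optional[tuple[int, int]] = None
        for rank, seq in sorted(parents):
            d = edit_distance(cluster.sequence, seq)
            if best is None or d < best[1]:
                best = (rank, d)
        assert best is not None
        cluster.nearest_parent = best
        cluster.intra_label = (
            IntraLabel.DIFF_1_2 if best[1] <= 2 else IntraLabel.DIFF_GT2
        )


def classify_amplicon(
    amplicon_id: str, reads: Sequence[SequenceRead]
) -> tuple[list[VariantCluster], list[SingletonRecord]]:
    """Cluster one amplicon's filtered reads and label every cluster."""
    clusters, singletons = cluster_reads(amplicon_id, reads)
    classify_intra(clusters)
    return clusters, singletons


def cluster_table(clusters: Sequence[VariantCluster]):
    """Cluster list as a tidy DataFrame (one row per cluster)."""
    import pandas as pd

    rows = []
    for c in clusters:
        rows.append(
            {
                "amplicon_id": c.amplicon_id,
                "rank": c.rank,
                "count": c.count,
                "frequency": c.frequency,
                "intra_label": c.intra_label.value if c.intra_label else None,
                "nearest_parent_rank": c.nearest_parent[0] if c.nearest_parent else None,
                "distance": c.nearest_parent[1] if c.nearest_parent else None,
                "chimera_left": c.chimera_parents[0] if c.chimera_parents else None,
                "chimera_right": c.chimera_parents[1] if c.chimera_parents else None,
                "breakpoint": c.chimera_parents[2] if c.chimera_parents else None,
                "sequence": c.sequence,
            }
        )
    return pd.DataFrame(rows)
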