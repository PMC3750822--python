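"""Replicate-based allele calling: from labelled clusters to genotypes.

Every individual is sequenced as two independent PCR replicates.  Because a
PCR or sequencing error is very unlikely to recur independently, a variant's
presence pattern across the replicate pair — combined with its intra-amplicon
artefact typology and its occurrence in other individuals — separates real
alleles from artefacts without any fixed frequency threshold.

The screen proceeds in two steps applied after intra-amplicon typing:

Step II (artefact screen, per individual)
    A ``DIFF_1_2`` or ``CHIMERA`` variant absent from the second replicate is
    a putative artefact, as is a variant typed ``CHIMERA`` in both
    replicates.  A ``DIFF_GT2`` variant absent from the second replicate is
    an artefact only if no other individual carries it.

Step III (allele call, iterated to a fixed point)
    A variant present in both replicates and strictly more frequent than
    every annotated artefact in both amplicons is a putative allele; present
    in both but not above the artefact bar it is an unclassified variant.  A
    ``DIFF_GT2`` seen in one replicate only is unclassified if the same
    sequence is an allele or unclassified variant elsewhere, otherwise an
    artefact.  A variant typed chimera in one replicate but differently in
    the other is accepted as a putative allele when other individuals carry
    it (a natural recombinant).  Because later artefact annotations can
    raise an amplicon's artefact bar, and cross-individual statuses evolve,
    the step repeats until no label changes.

A final census re-flags sequences called allele in some individuals but
unclassified in strictly more individuals as low-efficiency alleles: real
alleles whose weak, inconsistent amplification makes them prone to dropout.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .types import FinalLabel, IntraLabel, VariantCluster

#: Replicate pairs sharing no variant at all are treated as incongruent
#: (cross-contamination or a barcode swap) and the individual is excluded.
DEFAULT_MIN_AMPLICON_READS = 100


@dataclass
class CallingConfig:
    min_amplicon_reads: int = DEFAULT_MIN_AMPLICON_READS
    allele_prefix: str = "VAR-"


@dataclass
class CallingResult:
    """Outcome of the calling workflow for one dataset."""

    labels: dict[tuple[str, str], FinalLabel]  # (individual, sequence) -> label
    genotypes: pd.DataFrame
    allele_registry: dict[str, str]  # sequence -> stable allele name
    excluded: dict[str, str]  # individual -> reason
    low_efficiency_sequences: set[str]
    dropout_report: pd.DataFrame
    n_passes: int

    def genotype_of(self, individual_id: str) -> list[str]:
        sub = self.genotypes[self.genotypes.individual_id == individual_id]
        return sorted(sub.allele_name)


ClustersByIndividual = Mapping[str, Mapping[int, Sequence[VariantCluster]]]


def _index_by_sequence(
    clusters: Sequence[VariantCluster],
) -> dict[str, VariantCluster]:
    return {c.sequence: c for c in clusters}


def step2_artefact_screen(
    seq: str,
    c1: Optional[VariantCluster],
    c2: Optional[VariantCluster],
    shared_elsewhere: bool,
) -> Optional[FinalLabel]:
    """Provisional artefact label from the replicate presence pattern.

    ``c1``/``c2`` are the variant's clusters in the two replicates (``None``
    when absent, i.e. not present as a non-singleton cluster).
    ``shared_elsewhere`` says whether any other individual carries the
    sequence as a non-singleton cluster.  Returns ``PUTATIVE_ARTEFACT`` or
    ``None`` (pass through to step III).
    """
    l1 = c1.intra_label if c1 is not None else None
    l2 = c2.intra_label if c2 is not None else None
    if l1 is IntraLabel.CHIMERA and l2 is IntraLabel.CHIMERA:
        return FinalLabel.PUTATIVE_ARTEFACT
    for here, there in ((l1, c2), (l2, c1)):
        if there is None:
            if here in (IntraLabel.CHIMERA, IntraLabel.DIFF_1_2):
                return FinalLabel.PUTATIVE_ARTEFACT
            if here is IntraLabel.DIFF_GT2 and not shared_elsewhere:
                return FinalLabel.PUTATIVE_ARTEFACT
    return None


def classify_by_frequency_threshold(
    clusters: Sequence[VariantCluster], t2: float
) -> dict[str, FinalLabel]:
    """Baseline threshold classifier: allele iff frequency >= t2.

    Provided only to benchmark the replicate-based workflow against a fixed
    intra-amplicon frequency cut-off.
    """
    if not (0 < t2 < 1):
        raise ValueError("t2 must lie in (0, 1)")
    return {
        c.sequence: (
            FinalLabel.PUTATIVE_ALLELE
            if c.frequency >= t2
            else FinalLabel.PUTATIVE_ARTEFACT
        )
        for c in clusters
    }


def call_alleles(
    clusters_by_individual: ClustersByIndividual,
    config: CallingConfig | None = None,
    amplicon_read_counts: Mapping[str, int] | None = None,
) -> CallingResult:
    """Run steps II-III to a fixed point, then the low-efficiency census.

    Parameters
    ----------
    clusters_by_individual
        For each individual, the labelled cluster lists of its replicates
        keyed by replicate index (1 and 2).
    amplicon_read_counts
        Optional post-filter read count per amplicon id used for the
        minimum-depth exclusion; defaults to the sum of cluster counts.
    """
    config = config or CallingConfig()
    excluded: dict[str, str] = {}
    data: dict[str, tuple[dict[str, VariantCluster], dict[str, VariantCluster]]] = {}

    for ind, reps in sorted(clusters_by_individual.items()):
        if set(reps.keys()) != {1, 2}:
            excluded[ind] = f"expected replicates {{1, 2}}, got {sorted(reps)}"
            continue
        idx1, idx2 = _index_by_sequence(reps[1]), _index_by_sequence(reps[2])
        depth_ok = True
        for rep_index, clusters in sorted(reps.items()):
            if amplicon_read_counts is not None:
                depth = amplicon_read_counts.get(f"{ind}.{rep_index}", 0)
            else:
                depth = sum(c.count for c in clusters)
            if depth < config.min_amplicon_reads:
                excluded[ind] = (
                    f"replicate {rep_index} has {depth} reads "
                    f"(< {config.min_amplicon_reads})"
                )
                depth_ok = False
                break
        if not depth_ok:
            continue
        if idx1 and idx2 and not (idx1.keys() & idx2.keys()):
            excluded[ind] = "replicates share no variant (suspected swap)"
            continue
        data[ind] = (idx1, idx2)

    # Cross-individual presence: sequence -> individuals carrying it as a
    # non-singleton cluster in at least one amplicon.
    carriers: dict[str, set[str]] = {}
    for ind, (idx1, idx2) in data.items():
        for seq in idx1.keys() | idx2.keys():
            carriers.setdefault(seq, set()).add(ind)

    labels: dict[tuple[str, str], FinalLabel] = {}
    sticky: set[tuple[str, str]] = set()

    for ind, (idx1, idx2) in data.items():
        for seq in sorted(idx1.keys() | idx2.keys()):
            shared = len(carriers[seq] - {ind}) > 0
            verdict = step2_artefact_screen(
                seq, idx1.get(seq), idx2.get(seq), shared
            )
            if verdict is not None:
                labels[(ind, seq)] = verdict
                sticky.add((ind, seq))

    n_variants = sum(
        len(idx1.keys() | idx2.keys()) for idx1, idx2 in data.values()
    )
    max_passes = n_variants + 2
    n_passes = 0
    while True:
        n_passes += 1
        if n_passes > max_passes:
            raise RuntimeError(
                "allele calling failed to reach a fixed point; this "
                "indicates an internal logic error"
            )
        snapshot = dict(labels)

        def status_elsewhere(seq: str, ind: str) -> bool:
            """Sequence is allele or unclassified in some other individual
            (as labelled in the previous pass)."""
            for other in carriers.get(seq, ()):  # noqa: B023
                if other == ind:
                    continue
                lab = snapshot.get((other, seq))  # noqa: B023
                if lab in (FinalLabel.PUTATIVE_ALLELE, FinalLabel.UNCLASSIFIED):
                    return True
            return False

        new_labels: dict[tuple[str, str], FinalLabel] = {}
        for ind, (idx1, idx2) in data.items():
            bar1 = max(
                (
                    c.frequency
                    for seq, c in idx1.items()
                    if snapshot.get((ind, seq)) is FinalLabel.PUTATIVE_ARTEFACT
                ),
                default=0.0,
            )
            bar2 = max(
                (
                    c.frequency
                    for seq, c in idx2.items()
                    if snapshot.get((ind, seq)) is FinalLabel.PUTATIVE_ARTEFACT
                ),
                default=0.0,
            )
            for seq in sorted(idx1.keys() | idx2.keys()):
                key = (ind, seq)
                if key in sticky:
                    new_labels[key] = labels[key]
                    continue
                c1, c2 = idx1.get(seq), idx2.get(seq)
                if c1 is not None and c2 is not None:
                    lab_set = {c1.intra_label, c2.intra_label}
                    if (
                        IntraLabel.CHIMERA in lab_set
                        and len(lab_set) > 1
                        and len(carriers[seq] - {ind}) > 0
                    ):
                        # chimera in one replicate only, carried by other
                        # individuals: accepted as a natural recombinant
                        new_labels[key] = FinalLabel.PUTATIVE_ALLELE
                        continue
                    if c1.frequency > bar1 and c2.frequency > bar2:
                        new_labels[key] = FinalLabel.PUTATIVE_ALLELE
                    else:
                        new_labels[key] = FinalLabel.UNCLASSIFIED
                else:
                    present = c1 if c1 is not None else c2
                    assert present is not None
                    if present.intra_label is IntraLabel.DIFF_GT2:
                        if status_elsewhere(seq, ind):
                            new_labels[key] = FinalLabel.UNCLASSIFIED
                        else:
                            new_labels[key] = FinalLabel.PUTATIVE_ARTEFACT
                    else:
                        # rank-1 clusters carry no artefact typology; with no
                        # evidence either way an absence from the replicate
                        # leaves the variant unclassified.
                        new_labels[key] = FinalLabel.UNCLASSIFIED
        if new_labels == snapshot:
            labels = new_labels
            break
        labels = new_labels

    low_eff = flag_low_efficiency_alleles(labels)

    registry = _allele_registry(
        labels, prefix=config.allele_prefix
    )

    rows = []
    for ind, (idx1, idx2) in sorted(data.items()):
        for seq in sorted(idx1.keys() | idx2.keys()):
            lab = labels[(ind, seq)]
            if lab in (FinalLabel.PUTATIVE_ALLELE, FinalLabel.LOW_EFFICIENCY_ALLELE):
                c1, c2 = idx1.get(seq), idx2.get(seq)
                rows.append(
                    {
                        "individual_id": ind,
                        "allele_name": registry[seq],
                        "reads_rep1": c1.count if c1 else 0,
                        "reads_rep2": c2.count if c2 else 0,
                        "label": lab.value,
                        "sequence": seq,
                    }
                )
    genotypes = pd.DataFrame(
        rows,
        columns=[
            "individual_id", "allele_name", "reads_rep1", "reads_rep2",
            "label", "sequence",
        ],
    )

    dropout_rows = []
    for _, row in genotypes.iterrows():
        for rep, reads in ((1, row.reads_rep1), (2, row.reads_rep2)):
            if reads < 2:
                dropout_rows.append(
                    {
                        "individual_id": row.individual_id,
                        "allele_name": row.allele_name,
                        "replicate": rep,
                        "reads": reads,
                    }
                )
    dropout_report = pd.DataFrame(
        dropout_rows, columns=["individual_id", "allele_name", "replicate", "reads"]
    )

    return CallingResult(
        labels=labels,
        genotypes=genotypes,
        allele_registry=registry,
        excluded=excluded,
        low_efficiency_sequences=low_eff,
        dropout_report=dropout_report,
        n_passes=n_passes,
    )


def flag_low_efficiency_alleles(
    labels: dict[tuple[str, str], FinalLabel]
) -> set[str]:
    """Census across individuals; re-flags labels in place.

    A sequence called ``PUTATIVE_ALLELE`` in at least one individual but
    ``UNCLASSIFIED`` in strictly more individuals than it is an allele is
    re-flagged ``LOW_EFFICIENCY_ALLELE`` wherever it occurs: its read
    frequencies are too inconsistent across amplicons to trust, the typical
    signature of an allele that amplifies poorly and drops out.  Returns the
    set of flagged sequences (candidates for wet-lab confirmation).
    """
    census: dict[str, dict[FinalLabel, int]] = {}
    for (_, seq), lab in labels.items():
        census.setdefault(seq, {}).setdefault(lab, 0)
        census[seq][lab] += 1
    flagged = {
        seq
        for seq, counts in census.items()
        if counts.get(FinalLabel.PUTATIVE_ALLELE, 0) >= 1
        and counts.get(FinalLabel.UNCLASSIFIED, 0)
        > counts.get(FinalLabel.PUTATIVE_ALLELE, 0)
    }
    for key in list(labels):
        if key[1] in flagged:
            labels[key] = FinalLabel.LOW_EFFICIENCY_ALLELE
    return flagged


def _allele_registry(
    labels: dict[tuple[str, str], FinalLabel], prefix: str
) -> dict[str, str]:
    """Stable names for called allele sequences, ordered by sequence hash.

    Hash ordering keeps a sequence's name independent of which individuals
    happen to carry it in a given dataset.
    """
    called = sorted(
        {
            seq
            for (_, seq), lab in labels.items()
            if lab in (FinalLabel.PUTATIVE_ALLELE, FinalLabel.LOW_EFFICIENCY_ALLELE)
        },
        key=lambda s: hashlib.sha256(s.encode()).hexdigest(),
    )
    return {seq: f"{prefix}{i + 1:03d}" for i, seq in enumerate(called)}
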