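"""Core domain types shared across the genotyping pipeline.

The pipeline operates on dual-barcoded amplicon sequencing runs in which
every individual is amplified twice (two independent PCR replicates, each
with its own barcode combination).  The types here describe reads, the
amplicon layout, quality-filter settings, and the per-variant records that
the clustering and allele-calling stages produce.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes and the base sets they stand for.  Used for primer
#: matching: a degenerate primer position matches any base in its set.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "W": frozenset("AT"),
    "S": frozenset("CG"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYWSKMBDHV", "TGCANYRWSMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRead:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    read_id: str
    bases: str
    quals: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id}: {len(self.quals)} quality scores for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AmpliconSpec:
    """Barcode pair + primers defining one PCR replicate of one individual.

    Reads whose first 10 bases equal ``f_mid`` and whose last 10 bases equal
    the reverse complement of ``r_mid`` belong to this amplicon.  Primers may
    contain IUPAC degenerate positions.
    """

    individual_id: str
    replicate_index: int
    f_mid: str
    r_mid: str
    f_primer: str
    r_primer: str
    expected_target_length: int

    @property
    def amplicon_id(self) -> str:
        return f"{self.individual_id}.{self.replicate_index}"


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the read-quality filter cascade.

    min_read_length
        Reads substantially shorter than the expected construct are dropped
        before demultiplexing (default 250 bp).
    min_qual_fraction / min_phred
        Keep a read only if at least ``min_qual_fraction`` of its bases have
        Phred score strictly greater than ``min_phred``.
    allowed_indel_unit / max_indel_units
        Length deviations from the expected target must be a multiple of the
        indel unit (3 bp, one codon) and at most ``max_indel_units`` units;
        anything else is a reading-frame shift and is rejected.
    """

    min_read_length: int = 250
    min_qual_fraction: float = 0.95
    min_phred: int = 20
    allowed_indel_unit: int = 3
    max_indel_units: int = 2
    strict_quality: bool = True  # reject reads that carry no quality scores

    def __post_init__(self) -> None:
        if not (0 < self.min_qual_fraction <= 1):
            raise ValueError("min_qual_fraction must be in (0, 1]")
        if self.allowed_indel_unit < 1:
            raise ValueError("allowed_indel_unit must be >= 1")


@dataclass
class FilterReport:
    """Per-stage attrition counts of the filter cascade.

    Invariant: ``reads_in == reads_out + sum of all removed_*`` and every
    surviving read is assigned to exactly one amplicon.
    """

    reads_in: int = 0
    removed_short: int = 0
    removed_bad_mid: int = 0
    removed_bad_primer: int = 0
    removed_low_quality: int = 0
    removed_bad_length_or_frame: int = 0
    reads_out: int = 0
    per_amplicon: dict[str, int] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return (
            self.removed_short
            + self.removed_bad_mid
            + self.removed_bad_primer
            + self.removed_low_quality
            + self.removed_bad_length_or_frame
        )

    def check(self) -> None:
        if self.reads_in != self.reads_out + self.total_removed:
            raise AssertionError("filter report does not conserve reads")
        if sum(self.per_amplicon.values()) != self.reads_out:
            raise AssertionError("per-amplicon counts do not sum to reads_out")

    def to_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "removed_short": self.removed_short,
            "removed_bad_mid": self.removed_bad_mid,
            "removed_bad_primer": self.removed_bad_primer,
            "removed_low_quality": self.removed_low_quality,
            "removed_bad_length_or_frame": self.removed_bad_length_or_frame,
            "reads_out": self.reads_out,
            "per_amplicon": dict(self.per_amplicon),
        }


class IntraLabel(str, Enum):
    """Intra-amplicon category assigned to each non-singleton cluster."""

    TOP = "TOP"
    CHIMERA = "CHIMERA"
    DIFF_1_2 = "DIFF_1_2"
    DIFF_GT2 = "DIFF_GT2"


class FinalLabel(str, Enum):
    """Final per-(variant, individual) call after replicate reconciliation."""

    PUTATIVE_ALLELE = "PUTATIVE_ALLELE"
    PUTATIVE_ARTEFACT = "PUTATIVE_ARTEFACT"
    UNCLASSIFIED = "UNCLASSIFIED"
    LOW_EFFICIENCY_ALLELE = "LOW_EFFICIENCY_ALLELE"


@dataclass
class VariantCluster:
    """A set of identical reads within one amplicon.

    ``frequency`` is the intra-amplicon frequency computed over non-singleton
    reads only (singletons are treated as artefacts and excluded from the
    denominator).  ``nearest_parent`` records, for 1-2 bp / >2 bp categories,
    the rank of the most similar strictly-more-frequent cluster and the
    alignment distance to it.  ``chimera_parents`` records the certificate
    (rank of left parent, rank of right parent, breakpoint) when the chimera
    test fired.
    """

    amplicon_id: str
    sequence: str
    count: int
    rank: int
    frequency: float
    intra_label: Optional[IntraLabel] = None
    nearest_parent: Optional[tuple[int, int]] = None  # (parent rank, distance)
    chimera_parents: Optional[tuple[int, int, int]] = None


@dataclass(frozen=True)
class SingletonRecord:
    """A sequence observed exactly once in its amplicon (putative artefact)."""

    amplicon_id: str
    sequence: str
    read_id: str
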