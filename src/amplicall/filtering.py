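"""Read quality filtering and demultiplexing of dual-barcoded amplicon runs.

The cascade mirrors the standard pre-processing of a barcoded amplicon
sequencing run of a protein-coding target:

1. drop reads substantially shorter than the expected construct;
2. sort reads by their forward/reverse barcode (MID) pair, discarding reads
   whose barcodes match no sample-sheet entry exactly;
3. strip both MIDs and primers, rejecting reads whose primer regions do not
   match under IUPAC semantics;
4. drop low-quality reads (fraction of bases above the Phred floor);
5. keep only reads whose length deviates from the expected target by whole
   codons and whose fixed-frame translation contains no internal stop codon
   (an automated reading-frame check: the target is a coding exon, so any
   frameshift or nonsense codon marks a sequencing artefact).

Every input read is counted exactly once, either in an amplicon or in one of
the rejection categories of the :class:`~amplicall.types.FilterReport`.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .types import (
    IUPAC_SETS,
    AmpliconSpec,
    FilterConfig,
    FilterReport,
    SequenceRead,
    reverse_complement,
)

logger = logging.getLogger(__name__)

MID_LENGTH = 10

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def filter_by_length(
    reads: Iterable[SequenceRead], config: FilterConfig
) -> tuple[list[SequenceRead], int]:
    """Keep reads of at least ``config.min_read_length`` bases.

    Returns the kept reads and the number removed.  The boundary is
    inclusive: a read exactly at the minimum length is kept.
    """
    kept: list[SequenceRead] = []
    removed = 0
    for read in reads:
        if len(read) >= config.min_read_length:
            kept.append(read)
        else:
            removed += 1
    return kept, removed


def _check_unique_mids(specs: Sequence[AmpliconSpec]) -> None:
    seen: dict[tuple[str, str], str] = {}
    for spec in specs:
        key = (spec.f_mid, spec.r_mid)
        if key in seen:
            raise ValueError(
                f"duplicate MID pair {key} shared by amplicons "
                f"{seen[key]} and {spec.amplicon_id}"
            )
        seen[key] = spec.amplicon_id


def demultiplex(
    reads: Iterable[SequenceRead], specs: Sequence[AmpliconSpec]
) -> tuple[dict[str, list[SequenceRead]], int]:
    """Assign reads to amplicons by exact dual-barcode match.

    A read belongs to a spec when its first 10 bases equal the spec's
    forward MID and its last 10 bases equal the reverse complement of the
    spec's reverse MID.  Both read orientations are tried; a read matching
    in reverse orientation is reverse-complemented (qualities reversed)
    before being stored, so downstream stages always see insert-forward
    sequences.  Barcode matching is exact: MIDs are designed to differ at
    three or more positions, so a single sequencing error in a barcode
    makes the read unassignable rather than misassigned.
    """
    _check_unique_mids(specs)
    lookup = {
        (s.f_mid, reverse_complement(s.r_mid)): s.amplicon_id for s in specs
    }
    assigned: dict[str, list[SequenceRead]] = defaultdict(list)
    unassigned = 0
    for read in reads:
        if len(read) < 2 * MID_LENGTH:
            unassigned += 1
            continue
        key = (read.bases[:MID_LENGTH], read.bases[-MID_LENGTH:])
        amp = lookup.get(key)
        if amp is not None:
            assigned[amp].append(read)
            continue
        rc = reverse_complement(read.bases)
        key = (rc[:MID_LENGTH], rc[-MID_LENGTH:])
        amp = lookup.get(key)
        if amp is not None:
            flipped = SequenceRead(
                read.read_id,
                rc,
                None if read.quals is None else read.quals[::-1],
            )
            assigned[amp].append(flipped)
        else:
            unassigned += 1
    return dict(assigned), unassigned


def iupac_match(primer: str, region: str) -> bool:
    """True when ``region`` matches ``primer`` position-by-position under
    IUPAC semantics (degenerate primer codes match their base sets)."""
    if len(primer) != len(region):
        return False
    for p, b in zip(primer, region):
        allowed = IUPAC_SETS.get(p)
        if allowed is None or b not in allowed:
            return False
    return True


def strip_and_check_primers(
    read: SequenceRead, spec: AmpliconSpec
) -> Optional[SequenceRead]:
    """Strip both primers from a MID-trimmed read, or reject it.

    The read must start with the forward primer and end with the reverse
    complement of the reverse primer, each matching with zero mismatches
    under IUPAC semantics.  Returns the insert (with qualities sliced to
    match) or ``None`` for rejection.
    """
    fp, rp = spec.f_primer, reverse_complement(spec.r_primer)
    if len(read) < len(fp) + len(rp):
        return None
    if not iupac_match(fp, read.bases[: len(fp)]):
        return None
    if not iupac_match(rp, read.bases[-len(rp):]):
        return None
    start, stop = len(fp), len(read) - len(rp)
    quals = None if read.quals is None else read.quals[start:stop]
    return SequenceRead(read.read_id, read.bases[start:stop], quals)


def quality_filter(read: SequenceRead, config: FilterConfig) -> bool:
    """Keep iff the fraction of bases with Phred strictly greater than
    ``min_phred`` is at least ``min_qual_fraction``.

    Reads without quality scores are rejected in strict mode (the default)
    and kept with a warning otherwise.
    """
    if read.quals is None:
        if config.strict_quality:
            return False
        logger.warning("read %s has no qualities; kept", read.read_id)
        return True
    if len(read) == 0:
        return False
    good = sum(1 for q in read.quals if q > config.min_phred)
    return good / len(read.quals) >= config.min_qual_fraction


def has_internal_stop(seq: str) -> bool:
    """True if any complete codon of ``seq`` in frame 0 is a stop codon."""
    for i in range(0, len(seq) - len(seq) % 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return True
    return False


def check_length_and_frame(
    target: SequenceRead, spec: AmpliconSpec, config: FilterConfig
) -> bool:
    """Keep iff the insert length deviates from the expected target length
    by a bounded whole number of codons and the fixed-frame translation has
    no internal stop codon.

    This automates the visual reading-frame inspection one would otherwise
    perform on an alignment: only indels of whole amino acids are credible
    in a functional coding exon.
    """
    dev = abs(len(target) - spec.expected_target_length)
    unit = config.allowed_indel_unit
    if dev % unit != 0 or dev > config.max_indel_units * unit:
        return False
    return not has_internal_stop(target.bases)


def run_filter(
    reads: Iterable[SequenceRead],
    specs: Sequence[AmpliconSpec],
    config: FilterConfig | None = None,
) -> tuple[dict[str, list[SequenceRead]], FilterReport]:
    """Run the full cascade; returns per-amplicon insert reads and a report.

    Amplicons for which no read survives are present in the result with an
    empty list, so downstream stages can distinguish "no reads" from
    "amplicon unknown".
    """
    config = config or FilterConfig()
    report = FilterReport()
    reads = list(reads)
    report.reads_in = len(reads)

    kept, report.removed_short = filter_by_length(reads, config)
    logger.info("length filter: kept %d, removed %d", len(kept), report.removed_short)

    by_amp, report.removed_bad_mid = demultiplex(kept, specs)
    logger.info(
        "demultiplex: assigned %d, unassigned %d",
        sum(len(v) for v in by_amp.values()),
        report.removed_bad_mid,
    )

    spec_by_id = {s.amplicon_id: s for s in specs}
    out: dict[str, list[SequenceRead]] = {s.amplicon_id: [] for s in specs}
    for amp_id, amp_reads in by_amp.items():
        spec = spec_by_id[amp_id]
        for read in amp_reads:
            trimmed = read
            if len(trimmed) < 2 * MID_LENGTH:
                report.removed_bad_primer += 1
                continue
            insert_region = SequenceRead(
                trimmed.read_id,
                trimmed.bases[MID_LENGTH:-MID_LENGTH],
                None if trimmed.quals is None else trimmed.quals[MID_LENGTH:-MID_LENGTH],
            )
            target = strip_and_check_primers(insert_region, spec)
            if target is None:
                report.removed_bad_primer += 1
                continue
            if not quality_filter(read, config):
                report.removed_low_quality += 1
                continue
            if not check_length_and_frame(target, spec, config):
                report.removed_bad_length_or_frame += 1
                continue
            out[amp_id].append(target)

    report.reads_out = sum(len(v) for v in out.values())
    report.per_amplicon = {amp: len(v) for amp, v in out.items()}
    report.check()
    return out, report
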