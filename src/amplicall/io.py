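"""File formats: FASTQ reads, sample sheets, per-amplicon FASTA, reports."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import AmpliconSpec, FilterReport, SequenceRead


def read_fastq(path: str | Path) -> list[SequenceRead]:
    """Load a Sanger-encoded (Phred+33) FASTQ file."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        reads.append(SequenceRead(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(
            r.quals if r.quals is not None else [30] * len(r.bases)
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_sample_sheet(
    path: str | Path,
    f_primer: str,
    r_primer: str,
    expected_target_length: int,
) -> list[AmpliconSpec]:
    """Load a TSV with columns individual_id, replicate, f_mid, r_mid.

    Primer sequences and the expected insert length apply run-wide and come
    from the run configuration rather than the sheet.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "replicate", "f_mid", "r_mid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    specs = [
        AmpliconSpec(
            individual_id=row.individual_id,
            replicate_index=int(row.replicate),
            f_mid=row.f_mid.upper(),
            r_mid=row.r_mid.upper(),
            f_primer=f_primer.upper(),
            r_primer=r_primer.upper(),
            expected_target_length=expected_target_length,
        )
        for row in df.itertuples()
    ]
    return specs


def write_sample_sheet(specs: Sequence[AmpliconSpec], path: str | Path) -> None:
    pd.DataFrame(
        {
            "individual_id": [s.individual_id for s in specs],
            "replicate": [s.replicate_index for s in specs],
            "f_mid": [s.f_mid for s in specs],
            "r_mid": [s.r_mid for s in specs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_amplicon_fastas(
    by_amplicon: dict[str, list[SequenceRead]], outdir: str | Path
) -> list[Path]:
    """One FASTA of filtered insert sequences per amplicon (read IDs kept)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for amp_id, reads in sorted(by_amplicon.items()):
        path = outdir / f"{amp_id}.fasta"
        records = [
            SeqRecord(Seq(r.bases), id=r.read_id, description="") for r in reads
        ]
        SeqIO.write(records, str(path), "fasta")
        paths.append(path)
    return paths


def write_filter_report(report: FilterReport, prefix: str | Path) -> None:
    """Write the attrition report as both TSV (stages) and JSON (full)."""
    prefix = Path(prefix)
    d = report.to_dict()
    stages = {k: v for k, v in d.items() if k != "per_amplicon"}
    pd.DataFrame({"stage": list(stages), "reads": list(stages.values())}).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False
    )
    prefix.with_suffix(".json").write_text(json.dumps(d, indent=2))
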