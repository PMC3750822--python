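"""End-to-end orchestration: filter -> cluster -> call -> efficiency -> T1.

Each stage is a pure function of its inputs plus recorded seeds, and the
run manifest captures configuration, per-stage counts and the per-individual
coverage verdicts, so a run is reproducible and resumable stage by stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as aio
from .calling import CallingConfig, CallingResult, call_alleles
from .clustering import classify_amplicon, cluster_table
from .efficiency import (
    EfficiencySet,
    estimate_efficiencies,
    observations_from_genotypes,
)
from .filtering import run_filter
from .thresholds import CoverageConfig, t1_resampled_genotype, t1_simulated
from .types import AmpliconSpec, FilterConfig, FilterReport, SequenceRead, VariantCluster

logger = logging.getLogger(__name__)

ALL_STAGES = ("filter", "cluster", "call", "efficiency", "t1")


@dataclass
class PipelineResult:
    filter_report: FilterReport
    clusters: dict[str, list[VariantCluster]]
    calling: Optional[CallingResult] = None
    efficiencies: Optional[EfficiencySet] = None
    coverage: Optional[pd.DataFrame] = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    reads: Sequence[SequenceRead],
    specs: Sequence[AmpliconSpec],
    filter_config: FilterConfig | None = None,
    calling_config: CallingConfig | None = None,
    coverage_config: CoverageConfig | None = None,
    seed: int = 0,
    stages: Sequence[str] = ALL_STAGES,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the pipeline on in-memory reads.

    ``stages`` is a prefix of the full stage list; later stages require the
    earlier ones.  When ``outdir`` is given, every stage writes its tables
    before the next stage starts.
    """
    stages = tuple(stages)
    for want, need in (("cluster", "filter"), ("call", "cluster"),
                       ("efficiency", "call"), ("t1", "efficiency")):
        if want in stages and need not in stages:
            raise ValueError(f"stage {want!r} requires stage {need!r}")
    filter_config = filter_config or FilterConfig()
    calling_config = calling_config or CallingConfig()
    coverage_config = coverage_config or CoverageConfig(seed=seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": seed,
        "stages": list(stages),
        "filter_config": dataclasses.asdict(filter_config),
        "coverage_config": dataclasses.asdict(coverage_config),
        "n_input_reads": len(reads),
    }

    by_amplicon, report = run_filter(reads, specs, filter_config)
    manifest["filter"] = report.to_dict()
    if out is not None:
        aio.write_filter_report(report, out / "filter_report")
        aio.write_amplicon_fastas(by_amplicon, out / "amplicons")
    result = PipelineResult(filter_report=report, clusters={}, manifest=manifest)
    if "cluster" not in stages:
        _finish(result, out)
        return result

    clusters: dict[str, list[VariantCluster]] = {}
    n_singletons = 0
    for amp_id, amp_reads in sorted(by_amplicon.items()):
        cl, singles = classify_amplicon(amp_id, amp_reads)
        clusters[amp_id] = cl
        n_singletons += len(singles)
    result.clusters = clusters
    manifest["cluster"] = {
        "n_clusters": sum(len(v) for v in clusters.values()),
        "n_singletons": n_singletons,
    }
    if out is not None:
        all_clusters = [c for v in clusters.values() for c in v]
        cluster_table(all_clusters).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
    if "call" not in stages:
        _finish(result, out)
        return result

    spec_by_amp = {s.amplicon_id: s for s in specs}
    by_individual: dict[str, dict[int, list[VariantCluster]]] = {}
    for amp_id, cl in clusters.items():
        spec = spec_by_amp[amp_id]
        by_individual.setdefault(spec.individual_id, {})[spec.replicate_index] = cl
    calling = call_alleles(
        by_individual, calling_config, amplicon_read_counts=report.per_amplicon
    )
    result.calling = calling
    manifest["call"] = {
        "n_individuals_called": calling.genotypes.individual_id.nunique()
        if len(calling.genotypes)
        else 0,
        "n_alleles": len(calling.allele_registry),
        "n_low_efficiency": len(calling.low_efficiency_sequences),
        "excluded": calling.excluded,
        "n_passes": calling.n_passes,
    }
    if out is not None:
        calling.genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        calling.dropout_report.to_csv(out / "dropout.tsv", sep="\t", index=False)
    if "efficiency" not in stages:
        _finish(result, out)
        return result

    effs: Optional[EfficiencySet] = None
    if len(calling.genotypes):
        observations = observations_from_genotypes(calling.genotypes)
        if observations:
            effs = estimate_efficiencies(observations, seed=seed)
    result.efficiencies = effs
    manifest["efficiency"] = (
        None
        if effs is None
        else {
            "log_likelihood": effs.log_likelihood,
            "converged": effs.converged,
            "n_amplicons": effs.n_amplicons,
            "n_components": len(effs.components),
            "reference": effs.reference_allele,
            "duplication_candidates": sorted(effs.duplication_candidates),
        }
    )
    if out is not None and effs is not None:
        pd.DataFrame(
            {
                "allele_name": sorted(effs.relative),
                "relative": [effs.relative[a] for a in sorted(effs.relative)],
                "standardised": [
                    effs.standardised.get(a) for a in sorted(effs.relative)
                ],
            }
        ).to_csv(out / "efficiencies.tsv", sep="\t", index=False)
    if "t1" not in stages:
        _finish(result, out)
        return result

    result.coverage = coverage_report(calling, effs, coverage_config)
    manifest["t1"] = {
        "n_reliable": int(result.coverage.reliable.sum()),
        "n_individuals": int(len(result.coverage)),
    }
    if out is not None:
        result.coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    _finish(result, out)
    return result


def coverage_report(
    calling: CallingResult,
    effs: Optional[EfficiencySet],
    config: CoverageConfig,
) -> pd.DataFrame:
    """Per-individual T1 estimates and an a-posteriori adequacy verdict.

    For each genotype: a variable-efficiency simulated T1 (from estimated
    standardised efficiencies when available) and the per-replicate
    resampled T1.  A genotype is "reliable" when each replicate's
    allele-labelled read total reaches the genotype-level resampled T1 —
    the depth its own realised allele frequencies say is needed.
    """
    rows = []
    for ind, sub in calling.genotypes.groupby("individual_id"):
        counts1 = dict(zip(sub.allele_name, sub.reads_rep1.astype(int)))
        counts2 = dict(zip(sub.allele_name, sub.reads_rep2.astype(int)))
        r1, r2, geno_t1 = t1_resampled_genotype(counts1, counts2, config)
        t1_var = None
        if effs is not None:
            probs = [
                effs.standardised.get(a)
                for a in sub.allele_name
                if effs.standardised.get(a)
            ]
            if len(probs) == len(sub):
                t1_var = t1_simulated(probs, config).t1
        reads1, reads2 = sum(counts1.values()), sum(counts2.values())
        reliable = geno_t1 is not None and min(reads1, reads2) >= geno_t1
        rows.append(
            {
                "individual_id": ind,
                "k": len(sub),
                "allele_reads_rep1": reads1,
                "allele_reads_rep2": reads2,
                "t1_resampled_rep1": None if r1 is None else r1.t1,
                "t1_resampled_rep2": None if r2 is None else r2.t1,
                "t1_resampled": geno_t1,
                "t1_var_eff": t1_var,
                "reliable": bool(reliable),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "k", "allele_reads_rep1", "allele_reads_rep2",
            "t1_resampled_rep1", "t1_resampled_rep2", "t1_resampled",
            "t1_var_eff", "reliable",
        ],
    )


def _finish(result: PipelineResult, out: Optional[Path]) -> None:
    if out is not None:
        (out / "manifest.json").write_text(
            json.dumps(result.manifest, indent=2, default=str)
        )
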