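"""Synthetic dual-barcoded amplicon runs with full truth tables.

The generator emulates the error taxonomy of a PCR-amplified, deeply
sequenced multilocus target so that every pipeline stage can be tested
against known ground truth:

* per-individual genotypes drawn from a shared allele pool, with per-allele
  amplification efficiencies spanning more than an order of magnitude;
* single-breakpoint PCR chimeras, always strictly less abundant than both
  source alleles (template switching happens late in the PCR);
* 1-2 bp polymerase-error variants amplified to multi-copy clusters
  (errors from early cycles), always less abundant than their source;
* singleton substitution errors (late errors, seen once);
* 1 bp frameshift reads standing in for homopolymer miscalls;
* low-quality reads that trip the Phred filter.

Every emitted read carries exactly one provenance label in the truth table.
Two replicate amplicons with independent noise are generated per individual.
Identical configuration and seed give identical output, byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as aio
from .types import AmpliconSpec, SequenceRead, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]

#: degenerate primers flanking the simulated target (one IUPAC code each so
#: the IUPAC matching path is exercised on every run)
DEFAULT_F_PRIMER = "TGCAGGATCTYGAGCAACGT"
DEFAULT_R_PRIMER = "CATCGWTACGGAGTTCAGCG"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults mirror a dual-replicate barcoded amplicon study of a
    multilocus target: 36 individuals carrying 2-9 alleles each from a pool
    of 20, per-allele efficiencies log-uniform over [0.2, 2.4] (a 12-fold
    span), and read depths of 768 +/- 314 per amplicon.  Artefact knobs are
    scaled to desk size: a handful of chimera clusters per amplicon rather
    than dozens, with cluster sizes capped at a small fraction of the
    amplicon so artefact frequencies stay in the low percent range.
    """

    n_individuals: int = 36
    allele_pool_size: int = 20
    alleles_per_individual: tuple[int, int] = (2, 9)
    target_length: int = 228
    divergence_range: tuple[int, int] = (4, 30)
    efficiency_range: tuple[float, float] = (0.2, 2.4)
    efficiency_levels: Optional[tuple[float, ...]] = None
    leave_one_out_genotypes: bool = False
    reads_per_amplicon_mean: float = 768.0
    reads_per_amplicon_sd: float = 314.0
    reads_per_amplicon_min: int = 142
    chimera_clusters_mean: float = 7.0
    chimera_count_fraction: float = 0.012
    early_error_clusters_mean: float = 2.5
    early_error_max_count: int = 6
    singleton_rate: float = 0.03
    frameshift_read_fraction: float = 0.02
    low_quality_read_fraction: float = 0.03
    f_primer: str = DEFAULT_F_PRIMER
    r_primer: str = DEFAULT_R_PRIMER
    allele_prefix: str = "SIM-"

    def __post_init__(self) -> None:
        if self.target_length % 3 != 0:
            raise ValueError("target_length must be a multiple of 3")
        for rate in (
            self.singleton_rate,
            self.frameshift_read_fraction,
            self.low_quality_read_fraction,
            self.chimera_count_fraction,
        ):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Named study designs.

    ``paper-like``
        the default configuration above.
    ``efficiency-ladder``
        a controlled design for sensitivity/dropout experiments: a pool of
        10 alleles at fixed efficiency levels from 0.1 to 2.4, genotypes of
        9 alleles (each individual lacks exactly one pool allele), fixed
        high depth.  Genotype efficiency sums are nearly equal across
        individuals, which makes per-allele read expectations predictable
        and the call outcome attributable to the planted efficiency alone.
    """
    if name == "paper-like":
        base = SimulationConfig()
    elif name == "efficiency-ladder":
        base = SimulationConfig(
            n_individuals=10,
            allele_pool_size=10,
            efficiency_levels=(0.1, 0.4, 0.7, 0.9, 1.0, 1.1, 1.3, 1.5, 1.8, 2.4),
            leave_one_out_genotypes=True,
            reads_per_amplicon_mean=1200.0,
            reads_per_amplicon_sd=80.0,
            reads_per_amplicon_min=1000,
            chimera_clusters_mean=7.0,
            chimera_count_fraction=0.010,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return dataclasses.replace(base, **overrides) if overrides else base


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    reads: pd.DataFrame  # read_id, amplicon_id, kind, source, detail
    genotypes: dict[str, list[str]]  # individual -> allele names
    allele_sequences: dict[str, str]  # allele name -> target sequence
    efficiencies: dict[str, float]  # allele name -> true efficiency

    def planted_cluster_counts(self, amplicon_id: str) -> pd.DataFrame:
        sub = self.reads[self.reads.amplicon_id == amplicon_id]
        return (
            sub.groupby(["kind", "source"], dropna=False)
            .size()
            .reset_index(name="count")
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    specs: list[AmpliconSpec]
    reads: list[SequenceRead]
    truth: TruthTable


def _random_mids(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= 3."""
    mids: list[str] = []
    attempts = 0
    while len(mids) < n:
        attempts += 1
        if attempts > 20_000:
            raise RuntimeError("could not generate enough distinct barcodes")
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(sum(a != b for a, b in zip(cand, m)) >= 3 for m in mids):
            mids.append(cand)
    return mids


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_allele_pool(
    config: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Mutually distinct, codon-clean allele sequences.

    A base sequence of random non-stop codons is mutated per allele at
    random positions (substitutions that never create a stop codon); pools
    are redrawn until every pairwise distance falls within the configured
    divergence range.
    """
    n_codons = config.target_length // 3
    dmin, dmax = config.divergence_range
    lo, hi = max(1, (dmin + 1) // 2), max(1, dmax // 2)
    for _ in range(60):
        base = "".join(rng.choice(_CODONS, size=n_codons))
        pool = []
        for _ in range(config.allele_pool_size):
            n_sub = int(rng.integers(lo, hi + 1))
            seq = list(base)
            positions = rng.choice(config.target_length, size=n_sub, replace=False)
            for pos in positions:
                codon_start = (pos // 3) * 3
                for _attempt in range(20):
                    new = rng.choice([b for b in _BASES if b != seq[pos]])
                    trial = seq[codon_start : codon_start + 3].copy()
                    trial[pos - codon_start] = new
                    if "".join(trial) not in STOP_CODONS:
                        seq[pos] = new
                        break
            pool.append("".join(seq))
        ok = all(
            dmin <= _hamming(pool[i], pool[j]) <= dmax
            for i in range(len(pool))
            for j in range(i + 1, len(pool))
        )
        if ok and len(set(pool)) == len(pool):
            return pool
    raise RuntimeError(
        "could not satisfy the divergence constraints; widen the range"
    )


def _assign_efficiencies(
    config: SimulationConfig, names: Sequence[str], rng: np.random.Generator
) -> dict[str, float]:
    if config.efficiency_levels is not None:
        levels = list(config.efficiency_levels)
        if len(levels) != len(names):
            raise ValueError("efficiency_levels must match the pool size")
        return dict(zip(names, levels))
    lo, hi = config.efficiency_range
    draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(names)))
    return {name: float(e) for name, e in zip(names, draws)}


def _genotypes(
    config: SimulationConfig, names: Sequence[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    genotypes = {}
    for i in range(config.n_individuals):
        ind = f"IND{i + 1:03d}"
        if config.leave_one_out_genotypes:
            out = i % len(names)
            genotypes[ind] = [n for j, n in enumerate(names) if j != out]
        else:
            k = int(
                rng.integers(
                    config.alleles_per_individual[0],
                    config.alleles_per_individual[1] + 1,
                )
            )
            chosen = rng.choice(len(names), size=min(k, len(names)), replace=False)
            genotypes[ind] = [names[j] for j in sorted(chosen)]
    return genotypes


def _has_internal_stop(seq: str) -> bool:
    return any(
        seq[i : i + 3] in STOP_CODONS
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in _BASES if b != out[pos]])
    return "".join(out)


def _clean_quals(rng: np.random.Generator, length: int) -> tuple[int, ...]:
    q = rng.integers(33, 41, size=length)
    return tuple(int(x) for x in q)


def _bad_quals(rng: np.random.Generator, length: int) -> tuple[int, ...]:
    q = rng.integers(33, 41, size=length)
    n_bad = max(1, int(0.10 * length))  # >5% of bases at/below the floor
    bad = rng.choice(length, size=n_bad, replace=False)
    q[bad] = rng.integers(5, 16, size=n_bad)
    return tuple(int(x) for x in q)


def _realise_primer(primer: str, rng: np.random.Generator) -> str:
    from .types import IUPAC_SETS

    out = []
    for ch in primer:
        allowed = sorted(IUPAC_SETS[ch])
        out.append(allowed[0] if len(allowed) == 1 else rng.choice(allowed))
    return "".join(out)


def simulate_amplicon(
    genotype: Sequence[str],
    allele_seqs: dict[str, str],
    efficiencies: dict[str, float],
    n_reads: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    amplicon_id: str = "amp",
) -> tuple[list[tuple[str, str, dict]], int]:
    """Target sequences and truth rows for one amplicon.

    Returns (items, n_reads_used) where each item is
    ``(target_sequence, kind, detail)``; the caller wraps sequences with
    barcodes, primers and qualities.  Chimera and early-error cluster sizes
    are clipped strictly below their sources, so the abundance ordering the
    calling workflow assumes holds by construction.
    """
    if not genotype:
        raise ValueError("genotype must be non-empty")
    eff = np.array([efficiencies[a] for a in genotype], dtype=float)
    if np.any(eff <= 0):
        raise ValueError("efficiencies must be positive")

    n_frame = int(rng.binomial(n_reads, config.frameshift_read_fraction))
    n_lowq = int(rng.binomial(n_reads, config.low_quality_read_fraction))
    n_single = int(rng.binomial(n_reads, config.singleton_rate))
    n_chim_clusters = int(rng.poisson(config.chimera_clusters_mean))
    n_err_clusters = int(rng.poisson(config.early_error_clusters_mean))

    cap = max(2, int(round(config.chimera_count_fraction * n_reads)))
    chim_counts = [int(rng.integers(2, cap + 1)) for _ in range(n_chim_clusters)]
    err_counts = [
        int(rng.integers(2, config.early_error_max_count + 1))
        for _ in range(n_err_clusters)
    ]
    n_artefact = n_frame + n_lowq + n_single + sum(chim_counts) + sum(err_counts)
    n_clean = n_reads - n_artefact
    if n_clean < 4 * len(genotype):
        raise ValueError(
            f"{amplicon_id}: {n_reads} reads cannot accommodate the artefact "
            "load; increase depth or lower the artefact rates"
        )

    p = eff / eff.sum()
    counts = rng.multinomial(n_clean, p)

    items: list[tuple[str, str, dict]] = []
    for allele, c in zip(genotype, counts):
        items.extend(
            (allele_seqs[allele], "allele", {"source": allele}) for _ in range(c)
        )

    # planted artefacts must not collide with any pool allele, or a spliced
    # product could masquerade as a real allele carried by another individual
    taken = set(allele_seqs.values())

    # chimeras: splice two distinct genotype alleles at a breakpoint where
    # the product differs from both parents; abundance-weighted parents
    if len(genotype) >= 2:
        for want in chim_counts:
            for _attempt in range(40):
                i, j = rng.choice(len(genotype), size=2, replace=False, p=p)
                s1, s2 = allele_seqs[genotype[i]], allele_seqs[genotype[j]]
                b = int(rng.integers(1, len(s1)))
                product = s1[:b] + s2[b:]
                count = min(want, counts[i] - 1, counts[j] - 1)
                if count >= 2 and product not in taken and not _has_internal_stop(product):
                    taken.add(product)
                    detail = {
                        "source": f"{genotype[i]}|{genotype[j]}",
                        "breakpoint": b,
                        "sequence": product,
                    }
                    items.extend((product, "chimera", detail) for _ in range(count))
                    break

    # early-cycle polymerase errors: 1-2 bp variants in multiple copies
    for want in err_counts:
        for _attempt in range(40):
            i = int(rng.choice(len(genotype), p=p))
            src = allele_seqs[genotype[i]]
            n_mut = int(rng.integers(1, 3))
            pos = rng.choice(len(src), size=n_mut, replace=False)
            var = _mutate(src, pos, rng)
            count = min(want, counts[i] - 1)
            if count >= 2 and var not in taken and not _has_internal_stop(var):
                taken.add(var)
                detail = {
                    "source": genotype[i],
                    "positions": ",".join(map(str, sorted(pos))),
                    "sequence": var,
                }
                items.extend((var, "early_error", detail) for _ in range(count))
                break

    # late errors: one-off substitution variants
    for _ in range(n_single):
        for _attempt in range(40):
            i = int(rng.choice(len(genotype), p=p))
            src = allele_seqs[genotype[i]]
            var = _mutate(src, [int(rng.integers(len(src)))], rng)
            if var not in taken and not _has_internal_stop(var):
                taken.add(var)
                items.append((var, "singleton_error", {"source": genotype[i]}))
                break

    # homopolymer-style miscalls: +/- 1 bp frameshifts
    for _ in range(n_frame):
        i = int(rng.choice(len(genotype), p=p))
        src = allele_seqs[genotype[i]]
        pos = int(rng.integers(len(src)))
        if rng.random() < 0.5:
            var = src[:pos] + rng.choice(list(_BASES)) + src[pos:]
        else:
            var = src[:pos] + src[pos + 1 :]
        items.append((var, "frameshift", {"source": genotype[i]}))

    # reads failing the quality filter (sequence itself is clean)
    for _ in range(n_lowq):
        i = int(rng.choice(len(genotype), p=p))
        items.append((allele_seqs[genotype[i]], "low_quality", {"source": genotype[i]}))

    return items, len(items)


def simulate_dataset(config: SimulationConfig, seed: int) -> SimulatedDataset:
    """Full run: allele pool, genotypes, reads, sample sheet and truth."""
    rng = np.random.default_rng(seed)
    pool = simulate_allele_pool(config, rng)
    names = [f"{config.allele_prefix}{i + 1:03d}" for i in range(len(pool))]
    allele_seqs = dict(zip(names, pool))
    efficiencies = _assign_efficiencies(config, names, rng)
    genotypes = _genotypes(config, names, rng)

    n_amplicons = 2 * config.n_individuals
    n_mids = int(np.ceil(np.sqrt(n_amplicons))) + 1
    f_mids = _random_mids(rng, n_mids)
    r_mids = _random_mids(rng, n_mids)

    specs: list[AmpliconSpec] = []
    combo = 0
    for ind in genotypes:
        for rep in (1, 2):
            specs.append(
                AmpliconSpec(
                    individual_id=ind,
                    replicate_index=rep,
                    f_mid=f_mids[combo // n_mids],
                    r_mid=r_mids[combo % n_mids],
                    f_primer=config.f_primer,
                    r_primer=config.r_primer,
                    expected_target_length=config.target_length,
                )
            )
            combo += 1

    reads: list[SequenceRead] = []
    truth_rows = []
    read_no = 0
    for spec in specs:
        n_reads = max(
            config.reads_per_amplicon_min,
            int(
                round(
                    rng.normal(
                        config.reads_per_amplicon_mean, config.reads_per_amplicon_sd
                    )
                )
            ),
        )
        items, _ = simulate_amplicon(
            genotypes[spec.individual_id],
            allele_seqs,
            efficiencies,
            n_reads,
            config,
            rng,
            amplicon_id=spec.amplicon_id,
        )
        order = rng.permutation(len(items))
        for idx in order:
            target, kind, detail = items[idx]
            read_no += 1
            read_id = f"read{read_no:07d}"
            fp = _realise_primer(spec.f_primer, rng)
            rp = _realise_primer(spec.r_primer, rng)
            bases = spec.f_mid + fp + target + reverse_complement(rp) + reverse_complement(spec.r_mid)
            quals = (
                _bad_quals(rng, len(bases))
                if kind == "low_quality"
                else _clean_quals(rng, len(bases))
            )
            if rng.random() < 0.5:
                bases = reverse_complement(bases)
                quals = quals[::-1]
            reads.append(SequenceRead(read_id, bases, quals))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "amplicon_id": spec.amplicon_id,
                    "individual_id": spec.individual_id,
                    "kind": kind,
                    "source": detail.get("source", ""),
                    "detail": json.dumps(
                        {k: v for k, v in detail.items() if k != "source"},
                        sort_keys=True,
                    ),
                }
            )

    truth = TruthTable(
        reads=pd.DataFrame(truth_rows),
        genotypes=genotypes,
        allele_sequences=allele_seqs,
        efficiencies=efficiencies,
    )
    return SimulatedDataset(
        config=config, seed=seed, specs=specs, reads=reads, truth=truth
    )


def write_run(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTQ + sample sheet + truth tables + config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fastq": outdir / "reads.fastq",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth_reads": outdir / "truth_reads.tsv",
        "truth_genotypes": outdir / "truth_genotypes.tsv",
        "truth_alleles": outdir / "truth_alleles.tsv",
        "config": outdir / "config.json",
    }
    aio.write_fastq(dataset.reads, paths["fastq"])
    aio.write_sample_sheet(dataset.specs, paths["sample_sheet"])
    dataset.truth.reads.to_csv(paths["truth_reads"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"individual_id": ind, "allele_name": name}
            for ind, names in dataset.truth.genotypes.items()
            for name in names
        ]
    ).to_csv(paths["truth_genotypes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "allele_name": name,
                "efficiency": dataset.truth.efficiencies[name],
                "sequence": seq,
            }
            for name, seq in dataset.truth.allele_sequences.items()
        ]
    ).to_csv(paths["truth_alleles"], sep="\t", index=False)
    cfg = dataclasses.asdict(dataset.config)
    cfg["seed"] = dataset.seed
    paths["config"].write_text(json.dumps(cfg, indent=2, default=list))
    return paths
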