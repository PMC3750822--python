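"""Truth-table amplicon simulator: constraints, determinism, round trips."""
import numpy as np
import pytest

from amplicall.clustering import cluster_reads
from amplicall.filtering import run_filter
from amplicall.simulate import (
    SimulationConfig,
    preset_config,
    simulate_allele_pool,
    simulate_amplicon,
    simulate_dataset,
    write_run,
)

SMALL = SimulationConfig(
    n_individuals=3,
    allele_pool_size=6,
    alleles_per_individual=(2, 4),
    reads_per_amplicon_mean=250.0,
    reads_per_amplicon_sd=20.0,
    reads_per_amplicon_min=200,
)

NOISELESS = SimulationConfig(
    n_individuals=2,
    allele_pool_size=5,
    alleles_per_individual=(2, 3),
    reads_per_amplicon_mean=220.0,
    reads_per_amplicon_sd=0.0,
    reads_per_amplicon_min=220,
    chimera_clusters_mean=0.0,
    early_error_clusters_mean=0.0,
    singleton_rate=0.0,
    frameshift_read_fraction=0.0,
    low_quality_read_fraction=0.0,
)


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestAllelePool:
    def test_pool_respects_constraints(self):
        rng = np.random.default_rng(0)
        config = SimulationConfig(allele_pool_size=20)
        pool = simulate_allele_pool(config, rng)
        assert len(set(pool)) == 20
        assert all(len(s) == config.target_length for s in pool)
        lo, hi = config.divergence_range
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                assert lo <= _hamming(pool[i], pool[j]) <= hi
        from amplicall.filtering import has_internal_stop

        assert not any(has_internal_stop(s) for s in pool)

    def test_seeded_reproducibility(self):
        a = simulate_allele_pool(SMALL, np.random.default_rng(5))
        b = simulate_allele_pool(SMALL, np.random.default_rng(5))
        assert a == b


class TestAmplicon:
    def test_zero_error_rates_give_pure_multinomial_clusters(self):
        rng = np.random.default_rng(1)
        pool = simulate_allele_pool(NOISELESS, rng)
        seqs = {f"A{i}": s for i, s in enumerate(pool[:3])}
        items, n = simulate_amplicon(
            list(seqs), seqs, {k: 1.0 for k in seqs}, 300, NOISELESS, rng
        )
        assert n == 300
        assert all(kind == "allele" for _, kind, _ in items)

    def test_artefact_ordering_invariant(self):
        """Every planted chimera / amplified error is strictly less abundant
        than each of its sources."""
        rng = np.random.default_rng(2)
        config = SMALL
        pool = simulate_allele_pool(config, rng)
        seqs = {f"A{i}": s for i, s in enumerate(pool[:4])}
        eff = {"A0": 1.5, "A1": 1.0, "A2": 0.6, "A3": 0.3}
        items, _ = simulate_amplicon(list(seqs), seqs, eff, 700, config, rng)
        counts: dict[tuple[str, str], int] = {}
        for seq, kind, detail in items:
            counts[(kind, seq)] = counts.get((kind, seq), 0) + 1
        allele_counts = {
            detail["source"]: counts[("allele", seq)]
            for seq, kind, detail in items
            if kind == "allele"
        }
        for (kind, seq), n in counts.items():
            if kind == "chimera":
                detail = next(d for s, k, d in items if s == seq and k == kind)
                left, right = detail["source"].split("|")
                assert n < allele_counts[left] and n < allele_counts[right]
            elif kind == "early_error":
                detail = next(d for s, k, d in items if s == seq and k == kind)
                assert 2 <= n < allele_counts[detail["source"]]

    def test_depth_too_small_for_artefact_load(self):
        rng = np.random.default_rng(3)
        pool = simulate_allele_pool(SMALL, rng)
        seqs = {f"A{i}": s for i, s in enumerate(pool[:4])}
        with pytest.raises(ValueError, match="cannot accommodate"):
            simulate_amplicon(
                list(seqs), seqs, {k: 1.0 for k in seqs}, 15, SMALL, rng
            )


class TestDataset:
    def test_byte_level_determinism(self):
        a = simulate_dataset(SMALL, seed=9)
        b = simulate_dataset(SMALL, seed=9)
        assert [r.bases for r in a.reads] == [r.bases for r in b.reads]
        assert [r.quals for r in a.reads] == [r.quals for r in b.reads]
        assert a.truth.efficiencies == b.truth.efficiencies

    def test_truth_read_ids_bijective_with_reads(self):
        ds = simulate_dataset(SMALL, seed=4)
        assert sorted(ds.truth.reads.read_id) == sorted(
            r.read_id for r in ds.reads
        )
        assert len(ds.specs) == 2 * SMALL.n_individuals

    def test_noiseless_round_trip_recovers_planted_clusters(self):
        """Filter + cluster on noiseless output reproduce the planted
        per-amplicon allele counts exactly."""
        ds = simulate_dataset(NOISELESS, seed=6)
        by_amp, report = run_filter(ds.reads, ds.specs)
        assert report.total_removed == 0
        name_by_seq = {s: n for n, s in ds.truth.allele_sequences.items()}
        for spec in ds.specs:
            truth = ds.truth.reads[ds.truth.reads.amplicon_id == spec.amplicon_id]
            planted = truth.groupby("source").size().to_dict()
            clusters, singles = cluster_reads(
                spec.amplicon_id, by_amp[spec.amplicon_id]
            )
            got = {name_by_seq[c.sequence]: c.count for c in clusters}
            for s in singles:  # an allele drawn once is still planted truth
                got[name_by_seq[s.sequence]] = 1
            assert got == planted

    def test_filter_stage_exactness_on_labelled_corruption(self):
        """Each filter stage removes exactly the reads planted to trip it."""
        config = SimulationConfig(
            n_individuals=2,
            allele_pool_size=4,
            alleles_per_individual=(2, 3),
            reads_per_amplicon_mean=300.0,
            reads_per_amplicon_sd=0.0,
            reads_per_amplicon_min=300,
            chimera_clusters_mean=2.0,
            early_error_clusters_mean=1.0,
            singleton_rate=0.01,
            frameshift_read_fraction=0.05,
            low_quality_read_fraction=0.05,
        )
        ds = simulate_dataset(config, seed=8)
        by_amp, report = run_filter(ds.reads, ds.specs)
        truth = ds.truth.reads
        n_frame = int((truth.kind == "frameshift").sum())
        n_lowq = int((truth.kind == "low_quality").sum())
        assert report.removed_low_quality == n_lowq
        assert report.removed_bad_length_or_frame == n_frame
        assert report.removed_bad_mid == 0 and report.removed_bad_primer == 0
        kept_ids = {r.read_id for reads in by_amp.values() for r in reads}
        clean = set(truth[~truth.kind.isin(["frameshift", "low_quality"])].read_id)
        assert kept_ids == clean

    def test_write_run_emits_consistent_files(self, tmp_path):
        ds = simulate_dataset(NOISELESS, seed=2)
        paths = write_run(ds, tmp_path)
        from amplicall.io import read_fastq, read_sample_sheet

        reads = read_fastq(paths["fastq"])
        assert len(reads) == len(ds.reads)
        assert reads[0].bases == ds.reads[0].bases
        specs = read_sample_sheet(
            paths["sample_sheet"],
            ds.config.f_primer,
            ds.config.r_primer,
            ds.config.target_length,
        )
        assert [s.amplicon_id for s in specs] == [
            s.amplicon_id for s in ds.specs
        ]
        assert paths["config"].exists() and paths["truth_reads"].exists()

    def test_frequencies_track_efficiencies(self):
        """Observed allele counts match efficiency-proportional expectations
        (chi-square goodness of fit not rejected)."""
        from scipy.stats import chisquare

        config = SimulationConfig(
            n_individuals=1,
            allele_pool_size=4,
            alleles_per_individual=(4, 4),
            efficiency_levels=(1.2, 1.0, 0.6, 0.2),
            reads_per_amplicon_mean=2000.0,
            reads_per_amplicon_sd=0.0,
            reads_per_amplicon_min=2000,
            chimera_clusters_mean=0.0,
            early_error_clusters_mean=0.0,
            singleton_rate=0.0,
            frameshift_read_fraction=0.0,
            low_quality_read_fraction=0.0,
        )
        rejected = 0
        for seed in range(10):
            ds = simulate_dataset(config, seed=seed)
            truth = ds.truth.reads
            sub = truth[truth.amplicon_id == ds.specs[0].amplicon_id]
            counts = sub.groupby("source").size()
            eff = np.array([ds.truth.efficiencies[a] for a in counts.index])
            expected = eff / eff.sum() * counts.sum()
            _, p = chisquare(counts.to_numpy(), expected)
            if p < 0.01:
                rejected += 1
        assert rejected <= 1
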