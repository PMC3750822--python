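# amplicall

Replicate-based genotyping of multilocus amplicon sequencing data:
artefact-aware allele calling, per-allele amplification-efficiency
estimation, and read-depth confidence thresholds.

## The problem

Deep amplicon sequencing of a multigene family (the motivating case is the
MHC class II DRB exon of a non-model vertebrate, where one primer pair
co-amplifies 2–11 alleles per individual) produces read pools riddled with
PCR artefacts: chimeras spliced from two real templates, polymerase errors
amplified across cycles, homopolymer frameshifts and plain sequencing
noise. At the same time, primer–template mismatches make some alleles
amplify an order of magnitude less efficiently than others, so at finite
depth real alleles silently drop out of genotypes. Both effects corrupt
downstream estimates of allelic diversity and heterozygosity.

`amplicall` implements a genotyping workflow built on **independent
duplicate PCRs per individual**. Because an artefact is unlikely to recur
independently, the presence pattern of each variant across the replicate
pair — combined with its intra-amplicon artefact typology and its
occurrence in other individuals — separates alleles from artefacts without
any fixed frequency cut-off. A posteriori, the package quantifies how many
reads a genotype actually needed, given the amplification biases it shows.

## The methods at the core

**Allele/artefact workflow.** Within each amplicon, identical reads are
collapsed into clusters ranked by abundance; singletons are discarded as
putative artefacts. Each non-top cluster is typed `CHIMERA` (a
single-breakpoint splice of two strictly-more-frequent clusters),
`DIFF_1_2` (1–2 bp from its nearest more-frequent cluster) or `DIFF_GT2`
(&gt;2 bp). Replicate reconciliation then labels every variant
`PUTATIVE_ALLELE`, `PUTATIVE_ARTEFACT` or `UNCLASSIFIED`, iterating to a
fixed point because each newly annotated artefact raises the frequency bar
that allele calls must clear. A final census flags sequences called allele
in some individuals but unclassified in more as `LOW_EFFICIENCY_ALLELE` —
real alleles at risk of dropout.

**Amplification efficiency.** Each allele *a* gets a single relative
efficiency *e<sub>a</sub>*; for an amplicon of genotype *G* with *n* allele
reads the counts are modelled as
Multinomial(*n*, *p<sub>a</sub>* = *e<sub>a</sub>* / Σ<sub>b∈G</sub> *e<sub>b</sub>*).
Efficiencies are estimated by maximising the summed multinomial
log-likelihood over all amplicons (concave in log *e*; estimated per
connected component of the genotype-sharing graph) and standardised
against a reference allele; standardised values ≥ 2 suggest duplicated or
homozygous alleles.

**Coverage thresholds (T1).** T1 is the minimal depth *n* such that every
allele of a *k*-allele genotype receives at least *m* = 2 reads with
probability ≥ 99.9%. It is computed exactly under equal efficiencies
(a convolution of truncated binomials), by seeded Monte-Carlo under
estimated efficiencies, by resampling each amplicon's observed allele
frequencies (the genotype value is the max over the two replicates), and
as a planning grid over (*k*, minimum efficiency). For equal efficiencies
the exact values are 15, 27, 38, 50, 62, 75, 87, 100 reads for
*k* = 2 … 9.

## Worked example

The bundled simulator generates a dual-barcoded run with a truth table;
the pipeline runs on it end to end:

```python
from amplicall import (CoverageConfig, preset_config, simulate_dataset,
                       run_pipeline, t1_analytic)

config = preset_config("efficiency-ladder", n_individuals=6)
dataset = simulate_dataset(config, seed=42)
result = run_pipeline(
    dataset.reads, dataset.specs,
    coverage_config=CoverageConfig(n_sims=2000, n_resample_sims=500,
                                   n_reps=20, seed=42),
    seed=42,
)
```

This run filters 14,675 reads down to 13,978, calls 9 distinct alleles,
and for individual `IND002` reports a genotype of 8 alleles with read
counts agreeing across replicates, e.g.

```
allele_name  reads_rep1  reads_rep2           label
    VAR-004          93          75 PUTATIVE_ALLELE
    VAR-002         211         223 PUTATIVE_ALLELE
    ...
```

Estimated standardised efficiencies span 1.0–6.5 relative to the weakest
allele (`VAR-001`, the reference here), i.e. a &gt;6-fold amplification
bias. The coverage report compares each amplicon's allele-read total with
its resampled T1:

```
individual_id  k  t1_resampled  reliable
       IND001  9           278      True
       IND002  8           137      True
       ...
```

`reliable=True` means both replicates carry at least `t1_resampled`
allele reads, so a complete genotype would be recovered with 99.9%
confidence even under this individual's own skewed allele frequencies.
For comparison, `t1_analytic(9).t1` prints `100`: the depth that would
suffice for nine alleles *if* they amplified equally — the gap between
100 and 278 is the price of unequal amplification.

The same stages are exposed on the command line:

```bash
amplicall simulate --preset paper-like --seed 1 --out run/
amplicall run --fastq run/reads.fastq --sample-sheet run/sample_sheet.tsv \
    --f-primer TGCAGGATCTYGAGCAACGT --r-primer CATCGWTACGGAGTTCAGCG \
    --target-length 228 --out results/
amplicall t1 --k 9            # {"method": "analytic_equal", "k": 9, "t1": 100}
```

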