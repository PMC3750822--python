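# Methods

This note records the models, numerical choices and designed experimental
conditions behind `amplicall`, at the level of detail a maintainer or a
careful user needs.

## Read filtering

Reads pass a five-stage cascade: minimum length (default 250 bp, inclusive
boundary), exact dual-barcode demultiplexing, IUPAC primer matching with
zero mismatches, a Phred filter (keep iff ≥ 95% of bases have quality
strictly greater than 20), and a reading-frame check. Choices worth
spelling out:

* **Exact barcode matching.** Barcodes are designed to differ at ≥ 3
  positions, so one sequencing error in a barcode makes a read
  unassignable rather than misassigned. Tolerating mismatches would trade
  a small yield gain for cross-sample contamination risk; we keep the
  conservative reading.
* **Orientation.** Both read orientations are tried; reverse-orientation
  matches are reverse-complemented (qualities reversed) before primer
  stripping, so downstream stages see insert-forward sequences only.
* **Frame check as a proxy for visual inspection.** The target is a coding
  exon, so length deviations must be whole codons (default at most two
  3-bp units) and the fixed-frame translation must contain no stop codon.
  This automates what would otherwise be manual alignment inspection; it
  is a deliberate proxy and is configurable.
* An `N` inside the insert does not by itself reject a read — such a read
  becomes a singleton downstream and is discarded there; an `N` in a
  barcode or primer region fails the exact/IUPAC match.

Every input read lands in exactly one bucket (an amplicon or a rejection
category); the report asserts this conservation.

## Variant typology and chimera detection

Identical reads form clusters, ranked by count with lexicographic
tie-break (determinism). Singletons never form clusters; intra-amplicon
frequencies are computed over non-singleton reads only, so cluster
frequency comparisons are equivalent to count comparisons within an
amplicon.

The chimera test asks whether a query equals `left[:b] + right[b:]` for
two *distinct* clusters with *strictly* higher counts and some breakpoint
`b`. Strictness matters: the workflow's ordering assumption ("artefacts
are rarer than their sources") degenerates under count ties, so
equal-count clusters cannot source each other. The implementation
precomputes longest common prefixes/suffixes against the query, reducing
the test per parent pair to an interval-overlap check; parents whose
length differs from the query are handled by letting the splice consume
unequal amounts of each parent (single breakpoint, alignment-aware). Among
multiple certificates the lexicographically smallest
(left rank, right rank, breakpoint) is reported. Multi-breakpoint mosaics
are deliberately not searched — they land in the `>2 bp diff` category,
which the calling step treats with cross-individual scrutiny anyway.

Distance labels use a global (end-to-end) pairwise alignment distance
(edlib, unit costs), so codon-length indel variants that legitimately pass
the length filter remain comparable; each gap column counts one
difference. The chimera test runs before the distance labels: a cluster
that is both 1 bp from a parent and spliceable is a chimera.

## Replicate reconciliation and the fixed point

Step II (artefact screen) uses only static presence patterns: `1-2 bp
diff` or `chimera` absent from the partner replicate → artefact; chimera
in both replicates → artefact; `>2 bp diff` absent from the partner and
carried by no other individual → artefact. These labels are final
("sticky").

Step III recomputes, each pass: per-amplicon artefact frequency bars (the
maximum frequency over that individual's artefact-labelled variants);
allele calls (present in both replicates and strictly above the bar in
both); unclassified calls (present in both but not above the bar);
single-replicate `>2 bp diff` decisions (unclassified if the sequence is
allele/unclassified in another individual *as of the previous pass*,
artefact otherwise); and the natural-recombinant acceptance (chimera-typed
in one replicate, differently typed in the other, carried by other
individuals → allele). Passes are synchronous — every decision in pass
*t* reads only the labels of pass *t−1* — which makes the fixed point
independent of the order individuals are processed in. The step-III
cross-individual artefact labels are *not* sticky, so a variant provisionally
artefacted while its carrier elsewhere was still unresolved is revisited
once that carrier resolves. Convergence is guarded at `n_variants + 2`
passes; exceeding the guard raises, since it would indicate a logic error
rather than a hard dataset.

Design choices the workflow description leaves open, resolved here:

* Rank-1 (top) clusters carry no artefact typology; a top cluster absent
  from its partner replicate is `UNCLASSIFIED`, not artefact — there is no
  artefact-typology evidence against it, only missing confirmation.
* "More often unclassified" for the low-efficiency census means a strict
  majority of individuals; the census flag then flips every occurrence of
  the sequence.
* Only `PUTATIVE_ARTEFACT` frequencies set the bar; an unclassified
  variant's own frequency does not bar other variants.
* Replicate pairs sharing no variant at all are excluded as suspected
  contamination or barcode swaps; amplicons under 100 post-filter reads
  (configurable) exclude their individual.
* Allele names come from a hash-ordered registry, so a sequence's name
  does not depend on which individuals carry it in a given dataset.

## Efficiency model

The likelihood is a product of multinomial densities, one per amplicon,
with category probabilities proportional to the genotype's efficiencies.
In log-efficiency coordinates the log-likelihood is a sum of linear terms
minus log-sum-exp terms, hence concave; L-BFGS-B with an analytic gradient
converges reliably (gradient tolerance 1e−6, relative function tolerance
1e−12), and the default multi-start (5 seeded starts, first start at the
uniform point) guards numerics rather than multimodality. Positivity is
enforced by the log parameterisation; the scale degeneracy by pinning one
allele per connected component during optimisation. Standardisation (divide
by a reference allele) happens post hoc, which is equivalent up to the
removed scale.

Only ratios within a connected component of the genotype-sharing graph are
identifiable; the component structure is reported, standardisation covers
the reference's component only, and cross-component comparisons are
refused. Reads from census-flagged low-efficiency alleles are excluded
from the observations by construction of the genotype table (their counts
are unreliable by definition); a single-allele component gets efficiency 1
by convention.

The model assumes one efficiency per allele, constant across genotypes and
PCRs. The resampled T1 (below) is exactly the diagnostic for this
assumption: when per-amplicon realised frequencies disagree with the
fitted global efficiencies, resampled thresholds exceed the
variable-efficiency simulated ones.

## Coverage thresholds

`prob_all_at_least(n, p, m)` is computed exactly by sequential
conditioning: category 1's count is Binomial(n, p₁); given it, the rest is
a smaller multinomial. A dynamic programme convolves the truncated
binomials category by category — O(k·n²), no alternating sums (the usual
inclusion–exclusion identity is numerically fragile at large n), binomial
terms evaluated in log space. The kernel is exact for up to 15 categories;
beyond that callers are directed to the simulation path. Coverage
probability is monotone in n (adding a read cannot break coverage), so the
minimal n is found by doubling then bisection.

The Monte-Carlo estimator draws `n_sims` multinomial samples per candidate
depth and accepts a depth when the covered fraction reaches the
confidence; each of `n_reps` replications runs its own adaptive
doubling-plus-bisection search (deterministic given the seed), and the
reported T1 is the floor of the median across replications. At the
defaults (m = 2, 99.9%, 10,000 sims, 100 reps) the estimate stays within
three reads of the exact value for k ≤ 9; the residual spread reflects
binomial noise in estimating a 99.9% quantile from 10,000 draws, and is
why a simulation can report a value slightly *below* the exact threshold.

`m` defaults to 2 — one read is indistinguishable from a sequencing
error, and m = 2 is the setting that reproduces the exact threshold
column (k = 2 → 15). Both m and the confidence are configurable; the
planning grid can be emitted for m = 3 as well.

Resampling an amplicon's allele-labelled reads with replacement is
distributionally identical to a multinomial draw on its empirical allele
frequencies, so the resampled T1 reuses the simulator on empirical
frequencies (1,000 sims per candidate depth, 100 replications). An allele
with zero reads in an amplicon leaves that replicate's T1 undefined — the
zero itself is dropout evidence and is reported as such. The genotype
value is the maximum over the two replicates (depth must suffice under
either amplicon's realised bias). The pipeline's "reliable" verdict
compares each replicate's allele-read total against the genotype-level
resampled T1.

## The simulator: what it emulates, and what it does not

Defaults describe a plausible dual-replicate study: 36 individuals, a
20-allele pool, 2–9 alleles per genotype, efficiencies log-uniform on
[0.2, 2.4] (a 12-fold span), read depths 768 ± 314 per amplicon.
Artefacts follow the PCR error taxonomy: single-breakpoint chimeras of two
genotype alleles, strictly less abundant than both parents (template
switching is a late-cycle event); multi-copy 1–2 bp error clusters
strictly below their source (early-cycle errors get amplified); unique
singleton substitutions; ±1 bp frameshift reads; and low-quality reads
(10% of bases at Phred ≤ 15, tripping the 95%>Q20 rule deterministically).
Artefact cluster counts are scaled to desk size — a handful of chimera
clusters per amplicon with sizes capped near 1% of the amplicon — rather
than the dozens a real run shows; the *structure* (ordering constraints,
typology) is what upstream stages consume. Planted artefact sequences are
rejected if they collide with any pool allele or would contain an internal
stop codon (either would silently change their truth label downstream).

What the simulator does **not** model: platform-specific error profiles
(flow-space noise, position-dependent error rates), read-length
distributions, per-amplicon efficiency fluctuation (counts are exactly
multinomial in the planted efficiencies), cross-sample contamination and
barcode swaps (the corresponding exclusions are exercised with hand-built
fixtures instead). Passing tests therefore demonstrate correctness of the
classification logic under the stated error taxonomy, not robustness to
every real-world failure mode.

### The efficiency-ladder design

Sensitivity and dropout experiments use a controlled preset rather than
the continuous defaults: a pool of 10 alleles at fixed standardised
efficiency levels (0.1, 0.4, 0.7, 0.9, 1.0, 1.1, 1.3, 1.5, 1.8, 2.4),
leave-one-out genotypes of 9 alleles, ~1,200 reads per amplicon, chimera
cluster sizes capped at 1% of the amplicon. The design is chosen so the
outcome margins are provable a priori rather than seed-dependent: genotype
efficiency sums are nearly equal across individuals (9.7–12.0), so an
allele at level ≥ 0.4 expects ≥ 40 reads against an artefact bar of ~12
reads (a &gt;4σ Poisson margin — never demoted), while the 0.1-level
allele expects 10–13 reads, straddling the bar — sometimes called,
usually unclassified, hence census-flagged or recorded as dropout. With a
continuous efficiency draw these margins would depend on the luck of the
pool, and a sensitivity experiment that can fail for reasons other than
the code under test is a bad experiment.

The efficiency-recovery harness simulates amplicon *counts* directly
(36 individuals, continuous log-uniform efficiencies) at 2,500 reads per
amplicon: a Fisher-information calculation puts the 10% relative-error
check at roughly 4σ for the worst (lowest-efficiency) alleles at that
depth, versus ~2σ at 700 reads — the latter would make the check a coin
flip on the estimator's noise floor rather than a test of correctness.

## Known limitations

* Chimera detection considers single breakpoints only; true multi-fragment
  mosaics are classified by distance and survive only if replicated and
  above the artefact bar.
* Efficiencies are assumed allele-intrinsic; systematic per-run efficiency
  shifts would be attributed to noise and only surface through the
  resampled-vs-simulated T1 gap.
* The frequency-threshold classifier (`classify_by_frequency_threshold`)
  is a benchmarking baseline, not a recommended mode.
* Exact coverage probabilities are O(k·n²); for very deep amplicons with
  many alleles the simulation path is the practical route.
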