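"""Minimum read depth for reliable genotyping (the T1 family).

A genotype of ``k`` alleles is reliably covered at depth ``n`` when every
allele receives at least ``m`` reads (default 2: one read is
indistinguishable from a sequencing error) with probability at least a
stated confidence (default 99.9%).  Read counts are modelled as a
multinomial draw with per-allele probabilities proportional to
amplification efficiencies.  T1 is the smallest such ``n``, computed in
several flavours:

``analytic_equal``
    equal efficiencies, exact probability kernel, no simulation;
``simulated_equal`` / ``simulated_var_eff``
    Monte-Carlo estimate at uniform or efficiency-derived probabilities:
    the smallest depth at which at least a fraction ``confidence`` of
    ``n_sims`` multinomial draws covers every allele, median over
    ``n_reps`` replications;
``resampled``
    the same Monte-carlo estimate on one amplicon's *observed* allele
    frequencies (sampling reads with replacement is exactly a multinomial
    draw on the empirical frequencies), letting every amplicon carry its
    own efficiencies; at the genotype level the maximum over the two
    replicates is retained;
``min_eff_grid``
    a planning table of T1 over (number of alleles, minimum efficiency),
    with all other alleles at efficiency one.

All stochastic variants are seeded and record their configuration, so every
threshold is bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

#: largest number of alleles handled by the exact probability kernel before
#: callers are directed to the simulation path
EXACT_KERNEL_MAX_K = 15

_SEARCH_CAP = 10_000_000


@dataclass(frozen=True)
class CoverageConfig:
    """Settings shared by all T1 estimators.

    ``n_sims`` applies to the multinomial simulators; ``n_resample_sims``
    to the per-amplicon resampling variant, which is replicated on fewer
    draws because it runs once per amplicon.
    """

    m: int = 2
    confidence: float = 0.999
    n_sims: int = 10_000
    n_resample_sims: int = 1_000
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")
        if min(self.n_sims, self.n_resample_sims, self.n_reps) < 1:
            raise ValueError("simulation counts must be >= 1")


@dataclass
class CoverageThreshold:
    """One T1 estimate with its provenance."""

    method: str
    k: int
    t1: int
    config: CoverageConfig
    probs: Optional[tuple[float, ...]] = None
    per_rep: Optional[list[int]] = None
    seed: Optional[int] = None
    notes: str = ""


def prob_all_at_least(n: int, probs: Sequence[float], m: int = 2) -> float:
    """Exact P(every category count >= m) under Multinomial(n, probs).

    Computed by sequential conditioning: the count of the first category is
    binomial; given it, the remaining categories are multinomial on the
    leftover reads.  A dynamic programme convolves the truncated binomials
    category by category, which is exact in O(k n^2) and avoids the
    alternating sums of inclusion-exclusion.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p <= 0):
        raise ValueError("probabilities must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    k = len(p)
    if k > EXACT_KERNEL_MAX_K:
        raise ValueError(
            f"exact kernel supports at most {EXACT_KERNEL_MAX_K} categories; "
            "use the simulation path"
        )
    if n < k * m:
        return 0.0
    if k == 1:
        return 1.0
    tail = np.cumsum(p[::-1])[::-1]
    f = np.zeros(n + 1)
    f[n] = 1.0
    rows = np.arange(n + 1)[:, None]
    cols = np.arange(n + 1)[None, :]
    lgam = gammaln(np.arange(n + 2))
    for i in range(k - 1):
        q = p[i] / tail[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            logpmf = (
                lgam[rows + 1] - lgam[cols + 1] - lgam[rows - cols + 1]
                + cols * np.log(q) + (rows - cols) * np.log1p(-q)
            )
        pmf = np.where(cols <= rows, np.exp(logpmf), 0.0)
        new = np.zeros(n + 1)
        for r in np.nonzero(f)[0]:
            if r < m:
                continue
            c = np.arange(m, r + 1)
            new[r - c] += f[r] * pmf[r, m : r + 1]
        f = new
    return float(f[m:].sum())


def _min_n(success: Callable[[int], bool], start: int) -> int:
    """Smallest n with success(n), assuming success is (near-)monotone.

    Doubles from ``start`` to bracket the threshold, then bisects.
    """
    lo, hi = start - 1, start
    while not success(hi):
        lo, hi = hi, hi * 2
        if hi > _SEARCH_CAP:
            raise RuntimeError("T1 search exceeded the depth cap")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if success(mid):
            hi = mid
        else:
            lo = mid
    return hi


def t1_analytic(k: int, config: CoverageConfig | None = None) -> CoverageThreshold:
    """Exact T1 under equal amplification efficiencies.

    The smallest depth at which the exact coverage probability reaches the
    configured confidence, found by monotone search.
    """
    config = config or CoverageConfig()
    if k < 1:
        raise ValueError("k must be >= 1")
    p = tuple([1.0 / k] * k)
    t1 = _min_n(
        lambda n: prob_all_at_least(n, p, config.m) >= config.confidence,
        start=k * config.m,
    )
    return CoverageThreshold(
        method="analytic_equal", k=k, t1=t1, config=config, probs=p
    )


def _required_successes(config: CoverageConfig, n_sims: int) -> int:
    # smallest integer count whose fraction reaches the confidence
    return math.ceil(n_sims * config.confidence - 1e-9)


def _t1_one_replication(
    probs: np.ndarray,
    config: CoverageConfig,
    n_sims: int,
    rng: np.random.Generator,
) -> int:
    need = _required_successes(config, n_sims)
    m = config.m

    def success(n: int) -> bool:
        draws = rng.multinomial(n, probs, size=n_sims)
        return int((draws.min(axis=1) >= m).sum()) >= need

    return _min_n(success, start=len(probs) * m)


def t1_simulated(
    probs: Sequence[float],
    config: CoverageConfig | None = None,
    method: str = "simulated_var_eff",
    n_sims: int | None = None,
) -> CoverageThreshold:
    """Monte-Carlo T1 for given allele probabilities.

    One replication finds the smallest depth at which the configured
    fraction of multinomial draws covers all alleles; the reported T1 is
    the median over ``n_reps`` replications (ties in the median are
    resolved toward the lower value so the result stays an achieved depth).
    """
    config = config or CoverageConfig()
    p = np.asarray(probs, dtype=float)
    if np.any(p <= 0):
        raise ValueError("allele probabilities must be strictly positive")
    p = p / p.sum()
    sims = config.n_sims if n_sims is None else n_sims
    rng = np.random.default_rng(config.seed)
    values = [
        _t1_one_replication(p, config, sims, rng) for _ in range(config.n_reps)
    ]
    t1 = int(np.floor(np.median(values)))
    return CoverageThreshold(
        method=method,
        k=len(p),
        t1=t1,
        config=config,
        probs=tuple(p),
        per_rep=values,
        seed=config.seed,
    )


def t1_equal_simulated(
    k: int, config: CoverageConfig | None = None
) -> CoverageThreshold:
    """Monte-Carlo T1 under equal efficiencies (simulation analogue of
    :func:`t1_analytic`)."""
    res = t1_simulated([1.0 / k] * k, config, method="simulated_equal")
    return res


def t1_resampled(
    observed_counts: Mapping[str, int],
    config: CoverageConfig | None = None,
) -> Optional[CoverageThreshold]:
    """T1 from one amplicon's observed allele read counts.

    Reads are resampled with replacement from the amplicon's allele-labelled
    reads — distributionally a multinomial draw on the empirical allele
    frequencies — so every amplicon carries its own effective efficiencies.
    Returns ``None`` when an allele of the genotype has zero reads in this
    amplicon: the threshold is undefined and the zero itself is dropout
    evidence.
    """
    config = config or CoverageConfig()
    alleles = sorted(observed_counts)
    counts = np.array([observed_counts[a] for a in alleles], dtype=float)
    if np.any(counts == 0):
        return None
    probs = counts / counts.sum()
    res = t1_simulated(
        probs, config, method="resampled", n_sims=config.n_resample_sims
    )
    return res


def t1_resampled_genotype(
    counts_rep1: Mapping[str, int],
    counts_rep2: Mapping[str, int],
    config: CoverageConfig | None = None,
) -> tuple[Optional[CoverageThreshold], Optional[CoverageThreshold], Optional[int]]:
    """Per-replicate resampled T1 and the genotype-level value.

    The genotype-level threshold is the maximum over the two replicates
    (the conservative choice: depth must suffice under either amplicon's
    realised frequencies); it is undefined if both replicates show dropout.
    """
    config = config or CoverageConfig()
    r1 = t1_resampled(counts_rep1, config)
    r2 = t1_resampled(counts_rep2, replace(config, seed=config.seed + 1))
    values = [r.t1 for r in (r1, r2) if r is not None]
    return r1, r2, (max(values) if values else None)


def t1_min_efficiency_grid(
    k_values: Sequence[int],
    e_values: Sequence[float],
    config: CoverageConfig | None = None,
    exact: bool = True,
) -> pd.DataFrame:
    """Planning grid: T1 over allele counts and minimum efficiencies.

    For each (k, e) all alleles but one have efficiency 1 and the last has
    efficiency ``e``; T1 is computed exactly when the number of alleles is
    within the exact kernel's range (and ``exact`` is not disabled),
    otherwise by simulation.  The e = 1 column reduces to the
    equal-efficiency threshold.
    """
    config = config or CoverageConfig()
    rows = []
    for k in k_values:
        for e in e_values:
            if not (0 < e <= 1):
                raise ValueError("minimum efficiencies must lie in (0, 1]")
            probs = np.array([1.0] * (k - 1) + [e])
            probs = probs / probs.sum()
            if exact and k <= EXACT_KERNEL_MAX_K:
                t1 = _min_n(
                    lambda n: prob_all_at_least(n, probs, config.m)
                    >= config.confidence,
                    start=k * config.m,
                )
                method = "min_eff_grid_exact"
            else:
                t1 = t1_simulated(probs, config).t1
                method = "min_eff_grid_sim"
            rows.append({"k": k, "min_efficiency": e, "t1": t1, "method": method})
    return pd.DataFrame(rows)
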