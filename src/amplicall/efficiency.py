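"""Per-allele amplification efficiency by multinomial maximum likelihood.

A primer pair does not amplify every allele equally well: primer-template
mismatches make some alleles systematically under-represented in the read
pool, which at finite depth turns into allelic dropout.  The model assumes
each allele *a* has a single relative efficiency ``e_a``, independent of the
genotype it sits in and stable across PCRs.  For an amplicon whose
individual carries genotype ``G`` and produced ``n`` allele reads, the read
counts follow

    counts ~ Multinomial(n, p_a = e_a / sum_{b in G} e_b)  for a in G,

and the dataset log-likelihood is the sum of the multinomial log-densities
over all amplicons.  Efficiencies are estimated by maximising this function.
Only ratios within a connected component of the genotype-sharing graph are
identifiable (two alleles never co-amplified, even indirectly, cannot be
compared), so estimation runs per component with one allele pinned during
optimisation, and efficiencies are finally standardised against a
user-chosen reference allele (standardised efficiency of the reference = 1;
values >= 2 suggest a duplicated or homozygous allele).

The likelihood is concave in log-efficiencies (a sum of linear terms and
negated log-sum-exp terms), so the optimum is unique up to the pinned scale;
multiple starts guard the numerics rather than multimodality.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: standardised efficiency at or above which an allele is reported as a
#: candidate duplicated (or homozygous) allele
DUPLICATION_FLAG_THRESHOLD = 2.0


@dataclass(frozen=True)
class AmpliconObservation:
    """Allele read counts of one amplicon (putative-allele reads only)."""

    amplicon_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"amplicon {self.amplicon_id} has no allele counts")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"amplicon {self.amplicon_id} has negative counts")
        if sum(self.counts.values()) == 0:
            raise ValueError(f"amplicon {self.amplicon_id} has all-zero counts")


@dataclass
class EfficiencySet:
    """Fitted efficiencies with likelihood and convergence metadata."""

    relative: dict[str, float]
    reference_allele: str | None
    standardised: dict[str, float]
    log_likelihood: float
    converged: bool
    n_amplicons: int
    components: list[set[str]] = field(default_factory=list)
    duplication_candidates: set[str] = field(default_factory=set)
    seeds: list[int] = field(default_factory=list)


def genotype_loglik(
    efficiencies: Mapping[str, float],
    observations: Sequence[AmpliconObservation],
) -> float:
    """Multinomial log-likelihood of the observed counts.

    Each amplicon contributes ``log Multinomial(counts | n, p)`` with
    ``p_a`` proportional to the efficiencies of the alleles in that
    amplicon's genotype.  Scale-invariant: multiplying all efficiencies by a
    constant leaves the value unchanged.
    """
    total = 0.0
    for obs in observations:
        alleles = sorted(obs.counts)
        e = np.array([efficiencies[a] for a in alleles], dtype=float)
        if np.any(e <= 0):
            raise ValueError("efficiencies must be strictly positive")
        c = np.array([obs.counts[a] for a in alleles], dtype=float)
        n = c.sum()
        p = e / e.sum()
        total += float(
            gammaln(n + 1) - gammaln(c + 1).sum() + (c * np.log(p)).sum()
        )
    return total


def _connected_components(
    observations: Sequence[AmpliconObservation],
) -> list[set[str]]:
    """Components of the allele co-amplification graph (union-find)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for obs in observations:
        alleles = sorted(obs.counts)
        for a in alleles:
            parent.setdefault(a, a)
        for a in alleles[1:]:
            ra, r0 = find(a), find(alleles[0])
            if ra != r0:
                parent[ra] = r0
    groups: dict[str, set[str]] = {}
    for a in parent:
        groups.setdefault(find(a), set()).add(a)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])


def _fit_component(
    alleles: list[str],
    observations: Sequence[AmpliconObservation],
    n_starts: int,
    rng: np.random.Generator,
) -> tuple[dict[str, float], float, bool]:
    """Maximise the likelihood over one component (first allele pinned).

    Works on the log scale, which enforces positivity and removes the
    boundary; the pinned allele removes the scale degeneracy.
    """
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    obs_data = []
    for obs in observations:
        idx = np.array([index[a] for a in sorted(obs.counts)])
        cnt = np.array([obs.counts[a] for a in sorted(obs.counts)], dtype=float)
        obs_data.append((idx, cnt, cnt.sum()))

    def neg_ll_and_grad(theta_free: np.ndarray) -> tuple[float, np.ndarray]:
        theta = np.concatenate([[0.0], theta_free])
        ll = 0.0
        grad = np.zeros(k)
        for idx, cnt, n in obs_data:
            t = theta[idx]
            m = t.max()
            w = np.exp(t - m)
            z = w.sum()
            ll += float((cnt * t).sum() - n * (m + np.log(z)))
            grad[idx] += cnt - n * w / z
        return -ll, -grad[1:]

    best = None
    for start in range(max(1, n_starts)):
        x0 = np.zeros(k - 1) if start == 0 else rng.normal(0.0, 1.0, k - 1)
        res = minimize(
            neg_ll_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"gtol": 1e-6, "ftol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = np.concatenate([[0.0], best.x])
    rel = {a: float(np.exp(theta[index[a]])) for a in alleles}
    # add back the dropped multinomial coefficients for a full log-likelihood
    const = sum(
        float(gammaln(n + 1) - gammaln(cnt + 1).sum()) for _, cnt, n in obs_data
    )
    return rel, const - float(best.fun), bool(best.success)


def estimate_efficiencies(
    observations: Sequence[AmpliconObservation],
    reference_allele: str | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> EfficiencySet:
    """Maximum-likelihood relative efficiencies over all amplicons.

    Estimation runs independently on each connected component of the
    genotype-sharing graph.  A component with a single allele gets
    efficiency 1 by convention.  When ``reference_allele`` is given the
    result is standardised against it (see :func:`standardise`); otherwise
    the lexicographically first allele of the first component is used.
    """
    if not observations:
        raise ValueError("no observations")
    components = _connected_components(observations)
    rng = np.random.default_rng(seed)
    relative: dict[str, float] = {}
    total_ll = 0.0
    converged = True
    for comp in components:
        alleles = sorted(comp)
        comp_obs = [o for o in observations if set(o.counts) <= comp]
        if len(alleles) == 1:
            relative[alleles[0]] = 1.0
            total_ll += genotype_loglik({alleles[0]: 1.0}, comp_obs)
            continue
        rel, ll, ok = _fit_component(alleles, comp_obs, n_starts, rng)
        relative.update(rel)
        total_ll += ll
        converged = converged and ok

    result = EfficiencySet(
        relative=relative,
        reference_allele=None,
        standardised={},
        log_likelihood=total_ll,
        converged=converged,
        n_amplicons=len(observations),
        components=components,
        seeds=[seed],
    )
    if reference_allele is None:
        reference_allele = sorted(components[0])[0]
    return standardise(result, reference_allele)


def standardise(
    efficiencies: EfficiencySet, reference_allele: str
) -> EfficiencySet:
    """Divide efficiencies by the reference allele's efficiency.

    Only alleles in the reference's connected component are standardised;
    ratios across components are not identifiable and are refused.  Alleles
    whose standardised efficiency reaches 2 are flagged as candidate
    duplicated/homozygous alleles.
    """
    if reference_allele not in efficiencies.relative:
        raise KeyError(
            f"reference allele {reference_allele!r} not in estimated set; "
            f"available: {sorted(efficiencies.relative)}"
        )
    ref_component = next(
        comp for comp in efficiencies.components if reference_allele in comp
    )
    ref = efficiencies.relative[reference_allele]
    standardised = {
        a: efficiencies.relative[a] / ref for a in sorted(ref_component)
    }
    skipped = set(efficiencies.relative) - ref_component
    if skipped:
        logger.warning(
            "%d alleles outside the reference component were not "
            "standardised: %s",
            len(skipped),
            sorted(skipped),
        )
    efficiencies.reference_allele = reference_allele
    efficiencies.standardised = standardised
    efficiencies.duplication_candidates = {
        a
        for a, s in standardised.items()
        if s >= DUPLICATION_FLAG_THRESHOLD
    }
    return efficiencies


def observations_from_genotypes(genotypes) -> list[AmpliconObservation]:
    """Build per-amplicon observations from a genotype table.

    The table (as produced by :func:`amplicall.calling.call_alleles`) has one
    row per (individual, allele) with read counts in both replicates; each
    replicate becomes one observation.  Alleles with zero reads in a
    replicate are kept at count zero: a dropout is information, not a
    missing value.
    """
    obs = []
    for (ind,), sub in genotypes.groupby(["individual_id"]):
        for rep in (1, 2):
            counts = {
                row.allele_name: int(getattr(row, f"reads_rep{rep}"))
                for row in sub.itertuples()
            }
            if sum(counts.values()) > 0:
                obs.append(AmpliconObservation(f"{ind}.{rep}", counts))
    return obs
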