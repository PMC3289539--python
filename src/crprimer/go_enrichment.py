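"""GO-slim term enrichment among primer-bearing genes.

The study set (genes contributing at least one selected primer pair) is
compared against the population (all genes carrying at least one GO id)
with an exact hypergeometric test per term: upper-tail when the observed
count exceeds its expectation (over-representation), lower-tail otherwise
(under-representation).  The summation is done in exact integer arithmetic
— no normal approximation.

Alongside the exact p, each term gets a resampled mean and standard
deviation of its count under random study sets of the same size, and the
Z score (obs - mean)/sd, mirroring the classical over/under-representation
report layout (Obs. / Mean / S.D. / Z / p).  P-values are Bonferroni
corrected within each GO domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping

import numpy as np

from .seqio import ValidationError


def hypergeom_pvalue(
    obs: int, K_annotated: int, N_population: int, n_study: int
) -> tuple[float, str]:
    """Exact one-sided hypergeometric p-value and its direction.

    ``K_annotated`` genes of a population of ``N_population`` carry the
    term; a study set of ``n_study`` genes contains ``obs`` of them.  When
    ``obs`` is at or above the expectation n*K/N the upper tail
    P(X >= obs) is returned with direction "over", otherwise the lower
    tail P(X <= obs) with direction "under".
    """
    if not (0 <= K_annotated <= N_population and 0 <= n_study <= N_population):
        raise ValidationError("inconsistent hypergeometric counts")
    if not (0 <= obs <= min(K_annotated, n_study)):
        raise ValidationError(
            f"obs={obs} outside [0, min(K={K_annotated}, n={n_study})]"
        )
    total = comb(N_population, n_study)
    expected = n_study * K_annotated / N_population
    lo = max(0, n_study - (N_population - K_annotated))
    hi = min(K_annotated, n_study)
    if obs >= expected:
        num = sum(
            comb(K_annotated, k) * comb(N_population - K_annotated, n_study - k)
            for k in range(obs, hi + 1)
        )
        direction = "over"
    else:
        num = sum(
            comb(K_annotated, k) * comb(N_population - K_annotated, n_study - k)
            for k in range(lo, obs + 1)
        )
        direction = "under"
    return num / total, direction


def resample_null(
    annotation: Mapping[str, Iterable[str]],
    population: Iterable[str],
    n_study: int,
    reps: int = 10_000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Per-term (mean, sd) of annotated-gene counts in random study sets.

    Draws ``reps`` subsets of size ``n_study`` from the population without
    replacement (seeded, bit-reproducible) and tallies, for every GO term,
    how many sampled genes carry it.  The sd is the sample standard
    deviation (ddof=1).
    """
    genes = sorted(population)
    if n_study > len(genes):
        raise ValidationError("study set larger than population")
    if reps < 100:
        raise ValidationError("need at least 100 resampling replicates")
    terms = sorted({t for g in genes for t in annotation.get(g, ())})
    if not terms:
        return {}
    term_idx = {t: i for i, t in enumerate(terms)}
    member = np.zeros((len(genes), len(terms)), dtype=np.int64)
    for gi, g in enumerate(genes):
        for t in annotation.get(g, ()):
            member[gi, term_idx[t]] = 1
    rng = np.random.default_rng(seed)
    counts = np.empty((reps, len(terms)), dtype=np.int64)
    for r in range(reps):
        pick = rng.choice(len(genes), size=n_study, replace=False)
        counts[r] = member[pick].sum(axis=0)
    means = counts.mean(axis=0)
    sds = counts.std(axis=0, ddof=1)
    return {t: (float(means[i]), float(sds[i])) for t, i in term_idx.items()}


@dataclass(frozen=True)
class EnrichmentInput:
    """Population, study subset, slim annotations and the domain partition."""

    population: frozenset[str]
    study: frozenset[str]
    annotation: Mapping[str, frozenset[str]]
    domains: Mapping[str, str]  # GO id -> GO domain
    term_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study:
            raise ValidationError("empty study set")
        if not self.study <= self.population:
            raise ValidationError("study set is not a subset of the population")
        extra = set(self.annotation) - set(self.population)
        if extra:
            raise ValidationError(
                f"annotation covers genes outside the population: {sorted(extra)[:5]}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    go_id: str
    term: str
    domain: str
    obs: int
    mean: float
    sd: float
    z: float | None  # undefined (None) when sd == 0
    p: float
    p_adj: float
    direction: str
    significant: bool


def enrich(
    inputs: EnrichmentInput, reps: int = 10_000, seed: int = 0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term annotated to at least one population gene.

    Bonferroni multiplicity is the number of tested terms in the same GO
    domain (the report is organised per domain).  Results are sorted by
    adjusted p, then GO id.
    """
    pop = sorted(inputs.population)
    study = inputs.study
    N = len(pop)
    n = len(study)
    terms = sorted({t for g in pop for t in inputs.annotation.get(g, ())})
    null = resample_null(inputs.annotation, pop, n, reps=reps, seed=seed)

    m_by_domain: dict[str, int] = {}
    for t in terms:
        d = inputs.domains.get(t, "unknown")
        m_by_domain[d] = m_by_domain.get(d, 0) + 1

    results: list[EnrichmentResult] = []
    for t in terms:
        annotated = [g for g in pop if t in inputs.annotation.get(g, ())]
        K = len(annotated)
        obs = sum(1 for g in annotated if g in study)
        p, direction = hypergeom_pvalue(obs, K, N, n)
        mean, sd = null[t]
        z = None if sd == 0 else (obs - mean) / sd
        domain = inputs.domains.get(t, "unknown")
        p_adj = min(1.0, p * m_by_domain[domain])
        results.append(
            EnrichmentResult(
                go_id=t,
                term=inputs.term_names.get(t, t),
                domain=domain,
                obs=obs,
                mean=mean,
                sd=sd,
                z=z,
                p=p,
                p_adj=p_adj,
                direction=direction,
                significant=p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.go_id))
    return results
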