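"""De novo burden testing against a gene-level mutation-rate null.

The null model: across ``n`` screened chromosomes (2 per proband in an
autosomal gene), the number of qualifying de novo events in the gene is
Binomial(n, rate), where ``rate`` is a published per-chromosome mutation
rate derived from gene length and trinucleotide context. The test is the
one-sided upper tail including the observed count, P(X >= k); a Poisson
tail with lambda = n * rate is reported alongside as a cross-check, since
at these rates the two are nearly identical.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from scipy import stats

from .cohort_io import CohortTable, collapse_families

__all__ = [
    "EnrichmentResult",
    "expected_count",
    "binom_upper_tail",
    "poisson_upper_tail",
    "observed_denovo_count",
    "enrichment_test",
]

#: consequence classes that count toward the qualifying de novo burden
QUALIFYING_CONSEQUENCES = frozenset({"missense", "nonsense", "inframe_deletion"})


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected de novo counts with exact tail probabilities."""

    n_probands: int
    n_alleles: int
    rate_per_chromosome: float
    observed_denovo: int
    expected_denovo: float
    p_binomial_upper: float
    p_poisson_upper: float
    fold_enrichment: float

    def to_dict(self) -> dict:
        return asdict(self)


def expected_count(rate: float, n_probands: int) -> float:
    """Expected de novo events: 2 chromosomes per proband times the rate."""
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    if n_probands <= 0:
        raise ValueError(f"n_probands must be positive, got {n_probands}")
    return 2 * n_probands * rate


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), observed value included.

    Delegates to the regularized-incomplete-beta survival function, which
    is accurate deep in the tail (no term-by-term underflow).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), observed value included."""
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def observed_denovo_count(
    cohort: CohortTable,
    screened_sites: set[str] | None = None,
) -> int:
    """Count qualifying de novo alleles at the family level.

    Monozygotic twins collapse to one allele. Only variants with de novo
    inheritance and a qualifying consequence count. When ``screened_sites``
    is given, families from other sites are excluded — the denominator of
    the burden test only covers probands from systematically screened trio
    cohorts, so observations from unscreened sites must not inflate the
    numerator.
    """
    n = 0
    for rec in collapse_families(cohort):
        v = rec["variant"]
        if v.inheritance != "de_novo" or v.consequence not in QUALIFYING_CONSEQUENCES:
            continue
        if screened_sites is not None and rec["site"] not in screened_sites:
            continue
        n += 1
    return n


def enrichment_test(
    observed: int,
    n_probands: int,
    rate: float,
) -> EnrichmentResult:
    """Exact binomial (and Poisson) upper-tail test of de novo enrichment."""
    expected = expected_count(rate, n_probands)
    n_alleles = 2 * n_probands
    return EnrichmentResult(
        n_probands=n_probands,
        n_alleles=n_alleles,
        rate_per_chromosome=rate,
        observed_denovo=observed,
        expected_denovo=expected,
        p_binomial_upper=binom_upper_tail(observed, n_alleles, rate),
        p_poisson_upper=poisson_upper_tail(observed, expected),
        fold_enrichment=observed / expected,
    )
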