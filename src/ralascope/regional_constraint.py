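"""Regional missense depletion and codon-level recurrence.

The depletion test asks whether residues bearing population missense
variants avoid an annotated region (here, a nucleotide-binding pocket).
The unit of analysis is the residue: each residue either carries at least
one high-quality population missense variant or it does not, giving a 2x2
table (in/out of region x variant-bearing or not) with fixed margins,
tested by Fisher's exact test.

Two-sided convention: minimum-likelihood ("twin-tail") summation — all
tables with the observed margins whose hypergeometric point probability
does not exceed that of the observed table (within a small relative tie
tolerance) contribute to p. The one-sided lower tail (fewer variant
residues inside the region than expected) is reported alongside.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort_io import CohortTable, collapse_families
from .structure_contacts import RegionAnnotation

__all__ = [
    "DepletionTable",
    "RecurrenceSummary",
    "fisher_exact_two_sided",
    "build_depletion_table",
    "recurrence_summary",
    "read_population_variants",
    "recurrence_permutation_test",
]

#: relative tolerance when comparing point probabilities for the
#: minimum-likelihood two-sided sum (guards against float ties)
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class DepletionTable:
    """Residue-level 2x2 contingency of population variation vs a region."""

    region_size: int
    outside_size: int
    region_variant_residues: int
    outside_variant_residues: int
    p_fisher_two_sided: float
    p_hypergeom_lower: float
    degenerate: bool = False

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.region_variant_residues, self.region_size - self.region_variant_residues],
            [self.outside_variant_residues, self.outside_size - self.outside_variant_residues],
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table"] = self.table
        return d


@dataclass(frozen=True)
class RecurrenceSummary:
    """Codon-level counts of family-collapsed de novo alleles."""

    per_codon: dict[int, int]
    top_codons: list[tuple[int, int]]
    concentrated_alleles: int
    total_denovo_alleles: int

    def to_dict(self) -> dict:
        return {
            "per_codon": {str(k): v for k, v in sorted(self.per_codon.items())},
            "top_codons": [list(t) for t in self.top_codons],
            "concentrated_alleles": self.concentrated_alleles,
            "total_denovo_alleles": self.total_denovo_alleles,
        }


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> tuple[float, float, bool]:
    """Fisher's exact test on a 2x2 table.

    Returns ``(p_two_sided, p_lower_one_sided, degenerate)``. The
    two-sided p sums hypergeometric point probabilities over all tables
    with the observed margins that are no more probable than the observed
    one; the one-sided p is the lower tail on the top-left cell. An
    all-zero table is degenerate and reports p = 1.
    """
    (a, b), (c, d) = (int(x) for x in table[0]), (int(x) for x in table[1])
    if min(a, b, c, d) < 0:
        raise ValueError(f"table counts must be nonnegative, got {table}")
    n = a + b + c + d
    if n == 0:
        return 1.0, 1.0, True
    row1, col1 = a + b, a + c
    # support of the top-left cell given fixed margins
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p_two = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    p_lower = float(pmf[support <= a].sum())
    return min(p_two, 1.0), min(p_lower, 1.0), False


def build_depletion_table(
    region: RegionAnnotation,
    population_variant_residues: Iterable[int],
) -> DepletionTable:
    """Cross-tabulate variant-bearing residues against a region annotation.

    A residue carrying multiple population variants counts once: the
    question is whether variable *positions* avoid the region.
    """
    L = region.protein_length
    variant_res = set(int(r) for r in population_variant_residues)
    out_of_range = [r for r in variant_res if not 1 <= r <= L]
    if out_of_range:
        raise ValueError(
            f"variant residues outside [1, {L}]: {sorted(out_of_range)}"
        )
    in_region = set(region.residues)
    k_in = len(variant_res & in_region)
    k_out = len(variant_res - in_region)
    region_size = len(in_region)
    outside_size = L - region_size
    tab = [[k_in, region_size - k_in], [k_out, outside_size - k_out]]
    p_two, p_lower, degenerate = fisher_exact_two_sided(tab)
    return DepletionTable(
        region_size=region_size,
        outside_size=outside_size,
        region_variant_residues=k_in,
        outside_variant_residues=k_out,
        p_fisher_two_sided=p_two,
        p_hypergeom_lower=p_lower,
        degenerate=degenerate,
    )


def read_population_variants(path: str | Path) -> set[int]:
    """Read population variant residues from a list or an annotated TSV.

    Two formats are accepted: a plain residue-index list (one 1-based
    index per line, ``#`` comments allowed) or a TSV with columns
    ``residue``, ``consequence``, ``filter`` from which only PASS missense
    records are kept.
    """
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        return set()
    if "\t" in lines[0] and not lines[0].split("\t")[0].isdigit():
        rows = csv.DictReader(lines, delimiter="\t")
        required = {"residue", "consequence", "filter"}
        if not required <= set(rows.fieldnames or []):
            raise ValueError(
                f"{path}: annotated variant TSV needs columns {sorted(required)}"
            )
        return {
            int(row["residue"])
            for row in rows
            if row["filter"] == "PASS" and row["consequence"] == "missense"
        }
    return {int(ln.split("\t")[0]) for ln in lines}


def recurrence_summary(cohort: CohortTable, top_n: int = 2) -> RecurrenceSummary:
    """Count family-level de novo alleles per codon.

    Deletions are counted at their first deleted residue. ``top_codons``
    are ordered by descending count, ties broken by ascending codon index;
    ``concentrated_alleles`` is the number of alleles at the ``top_n``
    most recurrent codons.
    """
    per_codon: dict[int, int] = {}
    for rec in collapse_families(cohort):
        v = rec["variant"]
        if v.inheritance != "de_novo":
            continue
        per_codon[v.codon_index] = per_codon.get(v.codon_index, 0) + 1
    top = sorted(per_codon.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return RecurrenceSummary(
        per_codon=per_codon,
        top_codons=top,
        concentrated_alleles=sum(c for _, c in top),
        total_denovo_alleles=sum(per_codon.values()),
    )


def recurrence_permutation_test(
    cohort: CohortTable,
    protein_length: int,
    n_permutations: int = 10_000,
    top_n: int = 2,
    seed: int | None = None,
) -> float:
    """Permutation p for codon concentration (extension beyond the core
    descriptive report).

    Null: each de novo allele lands on a uniformly random codon. The
    statistic is the allele count at the ``top_n`` most recurrent codons.
    Returns P(statistic >= observed) with the observed arrangement
    included, so p is never 0.
    """
    obs = recurrence_summary(cohort, top_n=top_n)
    m = obs.total_denovo_alleles
    if m == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 1  # include the observed arrangement
    for _ in range(n_permutations):
        codons = rng.integers(1, protein_length + 1, size=m)
        counts = np.bincount(codons)
        stat = int(np.sort(counts)[-top_n:].sum())
        if stat >= obs.concentrated_alleles:
            hits += 1
    return hits / (n_permutations + 1)
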