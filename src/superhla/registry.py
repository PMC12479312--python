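"""Registry-level statistics: allele frequencies, homozygosity accounting and
Hardy-Weinberg equilibrium (HWE) testing.

Frequencies are simple call-count fractions: each of the ``n`` individuals
contributes two allele calls per gene, so ``freq(a) = count(a) / (2 n)``.
Homozygosity counts use *at-least* semantics — a triple homozygote also counts
in every pairwise and single-gene tally — matching how proportional Euler
diagrams of registry homozygotes are drawn; inclusion-exclusion then yields
union and exclusive counts.

The HWE test is a multi-allele chi-square: allele frequencies are estimated
from the observed genotype counts, expected counts are Hardy-Weinberg
proportions (n p_i^2 for homozygotes, 2 n p_i p_j for heterozygotes), and
genotype classes observed fewer than ``min_count`` times are excluded from
the chi-square sum (the asymptotic approximation is unreliable for rare
classes).  Degrees of freedom follow the m-allele formula
``m(m+1)/2 - m``; expected counts are deliberately not re-normalised after
filtering, so when classes are dropped the test is approximate — the result
carries an explicit caveat flag for that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import pandas as pd
from scipy import stats

from .nomenclature import GENES, Allele, Cohort, Gene, is_homozygous

__all__ = [
    "FrequencyTable",
    "HomozygosityCounts",
    "HweResult",
    "allele_frequencies",
    "genotype_counts",
    "triple_homozygote_haplotype_tally",
    "homozygosity_counts",
    "derive_union_and_exclusive",
    "hwe_expected",
    "hwe_chi_square",
]

#: Unordered allele pair used as a genotype-class key (canonically sorted).
GenotypeClass = tuple[Allele, Allele]


def _genotype_class(a: Allele, b: Allele) -> GenotypeClass:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-gene relative allele frequencies backed by ``n_individuals`` donors."""

    gene: Gene
    entries: Mapping[Allele, float]
    n_individuals: int

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("frequency table must be nonempty")
        object.__setattr__(self, "entries", dict(self.entries))
        total = sum(self.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        for a, f in self.entries.items():
            if a.gene is not self.gene:
                raise ValueError(f"{a} does not belong to {self.gene.long_name}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency of {a} out of [0, 1]: {f}")

    def __getitem__(self, allele: Allele) -> float:
        return self.entries.get(allele, 0.0)

    def alleles(self) -> list[Allele]:
        return sorted(self.entries)

    def top(self, m: int) -> list[tuple[Allele, float]]:
        """The ``m`` most frequent alleles (ties broken by name)."""
        ranked = sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:m]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"allele": a.canonical_text, "frequency": f}
            for a, f in sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_counts(cls, gene: Gene, counts: Mapping[Allele, int], n_individuals: int) -> "FrequencyTable":
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no allele calls to tabulate")
        # exact rational normalisation, converted to float at the end
        entries = {a: float(Fraction(c, total)) for a, c in counts.items() if c > 0}
        return cls(gene=gene, entries=entries, n_individuals=n_individuals)

    @classmethod
    def from_mapping(cls, gene: Gene, freqs: Mapping[Allele, float], n_individuals: int = 0,
                     renormalize: bool = False) -> "FrequencyTable":
        """Build from published frequencies, optionally renormalising to sum 1."""
        if not freqs:
            raise ValueError("frequency table must be nonempty")
        if renormalize:
            total = sum(freqs.values())
            if total <= 0:
                raise ValueError("frequencies sum to zero")
            freqs = {a: f / total for a, f in freqs.items()}
        return cls(gene=gene, entries=dict(freqs), n_individuals=n_individuals)


def allele_frequencies(cohort: Cohort, gene: Gene, k: int = 3) -> FrequencyTable:
    """Call-count allele frequencies at ``gene``, names truncated to ``k`` fields."""
    if len(cohort) == 0:
        raise ValueError("cannot compute frequencies on an empty cohort")
    counts: dict[Allele, int] = {}
    for g in cohort:
        for allele in g.alleles_at(gene, k):
            counts[allele] = counts.get(allele, 0) + 1
    return FrequencyTable.from_counts(gene, counts, n_individuals=len(cohort))


def genotype_counts(cohort: Cohort, gene: Gene, k: int = 3) -> dict[GenotypeClass, int]:
    """Observed unordered genotype-class counts at one gene."""
    counts: dict[GenotypeClass, int] = {}
    for g in cohort:
        key = _genotype_class(*g.alleles_at(gene, k))
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass(frozen=True)
class HomozygosityCounts:
    """At-least homozygosity tallies for the three class I genes."""

    per_gene: dict[Gene, int]
    per_pair: dict[frozenset[Gene], int]
    triple: int
    n: int

    def __post_init__(self) -> None:
        for pair, c in self.per_pair.items():
            g1, g2 = sorted(pair, key=lambda g: g.value)
            if not (self.triple <= c <= min(self.per_gene[g1], self.per_gene[g2])):
                raise ValueError(
                    f"pair count for {g1.long_name}/{g2.long_name} ({c}) violates "
                    f"nesting against triple={self.triple} and per-gene counts"
                )
        for g, c in self.per_gene.items():
            if c > self.n:
                raise ValueError(f"{g.long_name} count {c} exceeds cohort size {self.n}")


def homozygosity_counts(cohort: Cohort, k: int = 3) -> HomozygosityCounts:
    """Count individuals homozygous at each gene, gene pair, and all three genes.

    At-least semantics: an individual homozygous at all three genes contributes
    to every single and pairwise tally as well as the triple count.
    """
    per_gene = {g: 0 for g in GENES}
    pairs = [frozenset({GENES[0], GENES[1]}), frozenset({GENES[0], GENES[2]}),
             frozenset({GENES[1], GENES[2]})]
    per_pair = {p: 0 for p in pairs}
    triple = 0
    for g in cohort:
        homo = {gene for gene in GENES if is_homozygous(g, gene, k)}
        for gene in homo:
            per_gene[gene] += 1
        for p in pairs:
            if p <= homo:
                per_pair[p] += 1
        if len(homo) == 3:
            triple += 1
    return HomozygosityCounts(per_gene=per_gene, per_pair=per_pair, triple=triple, n=len(cohort))


def derive_union_and_exclusive(counts: HomozygosityCounts) -> tuple[int, int, int]:
    """Inclusion-exclusion on at-least homozygosity counts.

    Returns ``(at_least_one, exactly_two, exactly_one)``:

    - at_least_one = sum(per_gene) - sum(per_pair) + triple
    - exactly_two  = sum(per_pair) - 3 * triple
    - exactly_one  = at_least_one - exactly_two - triple
    """
    sum_single = sum(counts.per_gene.values())
    sum_pair = sum(counts.per_pair.values())
    at_least_one = sum_single - sum_pair + counts.triple
    exactly_two = sum_pair - 3 * counts.triple
    exactly_one = at_least_one - exactly_two - counts.triple
    if min(at_least_one, exactly_two, exactly_one) < 0 or at_least_one > counts.n:
        raise ValueError("inconsistent homozygosity counts")
    return at_least_one, exactly_two, exactly_one


def triple_homozygote_haplotype_tally(cohort: Cohort, k: int = 3) -> pd.DataFrame:
    """Tally the (A, B, C) allele triples of fully homozygous individuals.

    Triple homozygotes are the only individuals whose three-locus haplotype is
    unambiguous without phasing, so their haplotypes can be read directly off
    the genotype.  Rows are sorted by descending count, then by allele names.
    """
    tally: dict[tuple[Allele, Allele, Allele], int] = {}
    for g in cohort:
        if all(is_homozygous(g, gene, k) for gene in GENES):
            triple = tuple(g.alleles_at(gene, k)[0] for gene in GENES)
            tally[triple] = tally.get(triple, 0) + 1
    rows = [
        {
            "HLA-A": a.canonical_text,
            "HLA-B": b.canonical_text,
            "HLA-C": c.canonical_text,
            "count": n,
        }
        for (a, b, c), n in tally.items()
    ]
    df = pd.DataFrame(rows, columns=["HLA-A", "HLA-B", "HLA-C", "count"])
    if len(df):
        df = df.sort_values(
            by=["count", "HLA-A", "HLA-B", "HLA-C"], ascending=[False, True, True, True]
        ).reset_index(drop=True)
    return df


def hwe_expected(freq: FrequencyTable, n: int) -> dict[GenotypeClass, float]:
    """Hardy-Weinberg expected genotype counts for ``n`` individuals.

    Homozygote i/i: ``n p_i^2``; heterozygote i/j: ``2 n p_i p_j``.  Totals sum
    to ``n`` exactly (up to float rounding) because ``(sum p)^2 = 1``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    alleles = freq.alleles()
    expected: dict[GenotypeClass, float] = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            p, q = freq[a], freq[b]
            expected[_genotype_class(a, b)] = n * (p * p if a == b else 2 * p * q)
    return expected


@dataclass(frozen=True)
class HweResult:
    """Outcome of the multi-allele HWE chi-square test at one gene."""

    gene: Gene
    chi2: float
    df: int
    p_value: float
    n_alleles: int
    n_individuals: int
    retained_classes: list[GenotypeClass]
    observed: dict[GenotypeClass, int]
    expected: dict[GenotypeClass, float]
    n_filtered_classes: int
    #: True when rare classes were dropped but df kept the full-formula value,
    #: so the chi-square reference distribution is only approximate.
    df_filter_mismatch: bool = field(default=False)


def hwe_chi_square(
    observed: Mapping[GenotypeClass, int],
    min_count: int = 5,
    gene: Gene | None = None,
) -> HweResult:
    """Multi-allele Hardy-Weinberg chi-square test from observed genotype counts.

    Allele frequencies are estimated by counting alleles over *all* observed
    genotypes (before any filtering).  Genotype classes with observed count
    below ``min_count`` are excluded from the chi-square sum; degrees of
    freedom use ``m(m+1)/2 - m`` with ``m`` the number of distinct alleles
    observed.  With ``min_count=0`` this is the textbook test over every
    possible genotype class of the observed alleles.
    """
    if not observed:
        raise ValueError("no observed genotypes")
    total = sum(observed.values())
    if total <= 0:
        raise ValueError("no observed genotypes")
    allele_counts: dict[Allele, int] = {}
    for (a, b), c in observed.items():
        if c < 0:
            raise ValueError("negative genotype count")
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    if gene is None:
        gene = next(iter(allele_counts)).gene
    freq = FrequencyTable.from_counts(gene, allele_counts, n_individuals=total)
    expected = hwe_expected(freq, total)
    observed_full = {k: observed.get(k, 0) for k in expected}

    retained = [k for k, obs in observed_full.items() if obs >= min_count]
    if not retained:
        raise ValueError("nothing to test: every genotype class fell below min_count")
    chi2 = sum(
        (observed_full[k] - expected[k]) ** 2 / expected[k] for k in retained if expected[k] > 0
    )
    m = len(allele_counts)
    df = m * (m + 1) // 2 - m
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    n_filtered = len(expected) - len(retained)
    return HweResult(
        gene=gene,
        chi2=float(chi2),
        df=df,
        p_value=p_value,
        n_alleles=m,
        n_individuals=total,
        retained_classes=sorted(retained),
        observed={k: observed_full[k] for k in sorted(expected)},
        expected={k: expected[k] for k in sorted(expected)},
        n_filtered_classes=n_filtered,
        df_filter_mismatch=n_filtered > 0,
    )
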