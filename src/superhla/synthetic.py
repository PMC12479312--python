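"""Synthetic registries and toy HLA-like genes for end-to-end testing.

Real three-locus HLA data has two features that simple per-gene sampling
cannot produce: strong A-B-C linkage (haplotypes) and an excess of fully
homozygous individuals over the random-mating expectation.  The registry
model here captures both with a haplotype pool (triples of A/B/C alleles with
simplex weights) and a single whole-haplotype autozygosity parameter ``F``:
with probability ``F`` an individual receives two copies of one haplotype
(forcing triple homozygosity), otherwise two i.i.d. haplotypes.  Under this
model the triple-homozygote probability is ``F + (1 - F) * sum(w_h^2)``,
which gives a method-of-moments estimator for ``F``.

The toy gene builder emits small multi-exon genes with a CDS and a
transmembrane span, mimicking class I architecture at reduced scale, so the
guide-design cascade can be exercised without any sequence download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .nomenclature import GENES, Allele, Cohort, Gene, Genotype, parse_allele
from .guides import AnnotatedGeneSequence

__all__ = [
    "HaplotypePool",
    "RegistryModel",
    "sample_registry",
    "estimate_F",
    "published_triple_homozygote_cohort",
    "demo_haplotype_pool",
    "toy_gene_builder",
]

Haplotype = tuple[Allele, Allele, Allele]


@dataclass(frozen=True)
class HaplotypePool:
    """Distinct three-locus haplotypes with simplex weights."""

    haplotypes: tuple[Haplotype, ...]
    frequencies: tuple[float, ...]
    label: str = "pool"

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        if not self.haplotypes:
            raise ValueError("empty haplotype pool")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotypes must be distinct")
        total = sum(self.frequencies)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype weights sum to {total}, not 1")
        for h in self.haplotypes:
            for allele, gene in zip(h, GENES):
                if allele.gene is not gene:
                    raise ValueError(f"haplotype {h} has {allele} at the {gene.long_name} slot")

    def homozygosity_index(self) -> float:
        """Probability that two i.i.d. draws are the same haplotype (sum w^2)."""
        return float(sum(w * w for w in self.frequencies))


@dataclass(frozen=True)
class RegistryModel:
    """Synthetic registry: a haplotype pool, a size, and autozygosity excess F."""

    pool: HaplotypePool
    n: int
    F: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("registry size must be >= 1")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must be in [0, 1]")


def sample_registry(model: RegistryModel, label: str | None = None) -> Cohort:
    """Draw a cohort from the registry model; deterministic given the seed.

    Per individual: with probability ``F`` one haplotype is drawn and
    duplicated (whole-haplotype autozygosity); otherwise two haplotypes are
    drawn i.i.d. from the pool.
    """
    rng = np.random.default_rng(model.seed)
    weights = np.asarray(model.pool.frequencies, dtype=float)
    weights = weights / weights.sum()
    n_h = len(model.pool.haplotypes)
    autozygous = rng.random(model.n) < model.F
    first = rng.choice(n_h, size=model.n, p=weights)
    second = rng.choice(n_h, size=model.n, p=weights)
    second[autozygous] = first[autozygous]
    width = max(4, len(str(model.n)))
    genotypes = []
    for i in range(model.n):
        h1 = model.pool.haplotypes[int(first[i])]
        h2 = model.pool.haplotypes[int(second[i])]
        calls = {gene: (h1[j], h2[j]) for j, gene in enumerate(GENES)}
        genotypes.append(Genotype(individual_id=f"synth-{i:0{width}d}", calls=calls))
    return Cohort(genotypes, label=label or model.pool.label)


def estimate_F(cohort: Cohort, pool_frequencies: Sequence[float], k: int = 3) -> float:
    """Method-of-moments autozygosity estimate from triple-homozygote excess.

    With baseline triple-homozygosity ``h0 = sum(w^2)`` under random mating,
    the observed fraction ``h`` satisfies ``h = F + (1 - F) h0``, so
    ``F_hat = (h - h0) / (1 - h0)``.  Requires the (oracle) pool weights.
    """
    from .nomenclature import is_homozygous

    h0 = float(sum(w * w for w in pool_frequencies))
    if h0 >= 1.0:
        raise ValueError("degenerate pool (h0 = 1): F is unidentifiable")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n_triple = sum(
        all(is_homozygous(g, gene, k) for gene in GENES) for g in cohort
    )
    h_obs = n_triple / len(cohort)
    return (h_obs - h0) / (1.0 - h0)


def published_triple_homozygote_cohort() -> Cohort:
    """The 51 fully homozygous donors of the source registry survey, as a cohort.

    Fifteen distinct A-B-C haplotypes with published per-haplotype counts
    (summing to 51), each donor homozygous for one haplotype; bundled as a
    data asset so homozygosity tallies have a fixed, externally published
    reference point.
    """
    path = resources.files("superhla").joinpath("data/triple_homozygote_haplotypes.csv")
    df = pd.read_csv(str(path))
    genotypes = []
    i = 1
    for _, row in df.iterrows():
        hap = (
            parse_allele(row["HLA-A"]),
            parse_allele(row["HLA-B"]),
            parse_allele(row["HLA-C"]),
        )
        for _ in range(int(row["count"])):
            calls = {gene: (hap[j], hap[j]) for j, gene in enumerate(GENES)}
            genotypes.append(Genotype(individual_id=f"SD{i:02d}", calls=calls))
            i += 1
    return Cohort(genotypes, label="published-triple-homozygotes")


def demo_haplotype_pool(n_extra: int = 25, seed: int = 0) -> HaplotypePool:
    """Illustrative pool: the 15 published triple-homozygous haplotypes plus
    ``n_extra`` invented heterogeneous haplotypes, with Zipf-like weights.

    This is a demo structure, not an estimate of any real population's
    haplotype distribution.
    """
    path = resources.files("superhla").joinpath("data/triple_homozygote_haplotypes.csv")
    df = pd.read_csv(str(path))
    haplotypes: list[Haplotype] = [
        (parse_allele(r["HLA-A"]), parse_allele(r["HLA-B"]), parse_allele(r["HLA-C"]))
        for _, r in df.iterrows()
    ]
    rng = np.random.default_rng(seed)
    seen = set(haplotypes)
    while len(haplotypes) < 15 + n_extra:
        hap = (
            Allele(Gene.A, (int(rng.integers(1, 80)), int(rng.integers(1, 99)), 1)),
            Allele(Gene.B, (int(rng.integers(1, 80)), int(rng.integers(1, 99)), 1)),
            Allele(Gene.C, (int(rng.integers(1, 18)), int(rng.integers(1, 99)), 1)),
        )
        if hap not in seen:
            seen.add(hap)
            haplotypes.append(hap)
    ranks = np.arange(1, len(haplotypes) + 1, dtype=float)
    weights = 1.0 / ranks
    weights /= weights.sum()
    return HaplotypePool(
        haplotypes=tuple(haplotypes),
        frequencies=tuple(float(w) for w in weights),
        label="demo-pool",
    )


def product_pool(
    marginals: dict[Gene, dict[Allele, float]] | None = None,
    alleles_per_gene: int = 3,
    label: str = "product-pool",
) -> HaplotypePool:
    """Haplotype pool with independent loci: every A-B-C combination of the
    per-gene marginals, weighted by the product of marginal frequencies.

    With no argument, builds the equifrequent calibration pool
    (``alleles_per_gene`` alleles per gene): under F = 0 every gene is exactly
    at Hardy-Weinberg proportions, and at moderate cohort sizes every genotype
    class is common enough that rare-class filtering never engages — the
    setting in which the chi-square test's nominal size can be checked.
    """
    if marginals is None:
        marginals = {
            gene: {
                Allele(gene, (i, 1, 1)): 1.0 / alleles_per_gene
                for i in range(1, alleles_per_gene + 1)
            }
            for gene in GENES
        }
    haplotypes: list[Haplotype] = []
    weights: list[float] = []
    for a, wa in marginals[Gene.A].items():
        for b, wb in marginals[Gene.B].items():
            for c, wc in marginals[Gene.C].items():
                haplotypes.append((a, b, c))
                weights.append(wa * wb * wc)
    total = sum(weights)
    return HaplotypePool(
        haplotypes=tuple(haplotypes),
        frequencies=tuple(w / total for w in weights),
        label=label,
    )


def toy_gene_builder(
    gene: Gene = Gene.A,
    n_exons: int = 8,
    exon_lengths: Sequence[int] = (137, 270, 276, 276, 117, 33, 48, 143),
    intron_lengths: Sequence[int] = (130, 241, 580, 101, 442, 142, 169),
    utr5_length: int = 40,
    utr3_length: int = 120,
    tm_residues: tuple[int, int] = (326, 350),
    n_alleles: int = 1,
    n_variant_positions: int = 4,
    seed: int | None = None,
) -> list[AnnotatedGeneSequence]:
    """Build a toy multi-exon gene and allele variants of it.

    The defaults mimic class I scale: 8 exons, a ~1.1 kb CDS beginning after a
    short 5'UTR in exon 1 and ending before a 3'UTR in the last exon, and a
    transmembrane helix encoded in exon 5.  Alleles beyond the first differ
    from the reference at ``n_variant_positions`` randomly chosen exonic
    positions (never inside the start codon).  Deterministic given the seed.

    Raises
    ------
    ValueError
        If lengths are inconsistent (exon/intron counts, UTRs not fitting in
        the terminal exons, CDS not divisible by 3, TM outside the protein).
    """
    exon_lengths = tuple(int(x) for x in exon_lengths)
    intron_lengths = tuple(int(x) for x in intron_lengths)
    if len(exon_lengths) != n_exons:
        raise ValueError(f"expected {n_exons} exon lengths, got {len(exon_lengths)}")
    if len(intron_lengths) != n_exons - 1:
        raise ValueError(f"expected {n_exons - 1} intron lengths, got {len(intron_lengths)}")
    if utr5_length >= exon_lengths[0] or utr3_length >= exon_lengths[-1]:
        raise ValueError("UTRs must fit inside the terminal exons")
    cds_len = sum(exon_lengths) - utr5_length - utr3_length
    if cds_len <= 0 or cds_len % 3 != 0:
        raise ValueError(f"CDS length {cds_len} is not a positive multiple of 3")
    if n_alleles < 1:
        raise ValueError("need at least one allele")

    rng = np.random.default_rng(seed)
    exons = []
    pos = 0
    for i, length in enumerate(exon_lengths):
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += intron_lengths[i]
    total_len = pos
    bases = np.array(list("ACGT"))
    sequence = list("".join(rng.choice(bases, size=total_len)))
    cds_start = exons[0][0] + utr5_length
    cds_end = exons[-1][1] - utr3_length
    sequence[cds_start: cds_start + 3] = list("ATG")  # start codon for realism

    exonic_positions = [p for start, end in exons for p in range(start, end)]
    forbidden = set(range(cds_start, cds_start + 3))
    candidates = [p for p in exonic_positions if p not in forbidden]

    def build(name_fields: tuple[int, ...], seq_list: list[str]) -> AnnotatedGeneSequence:
        return AnnotatedGeneSequence(
            allele=Allele(gene=gene, fields=name_fields),
            sequence="".join(seq_list),
            exons=tuple(exons),
            cds_start=cds_start,
            cds_end=cds_end,
            tm_protein_span=tuple(int(r) for r in tm_residues),
            tm_includes_signal_peptide=True,
        )

    panel = [build((99, 1, 1), sequence)]
    for a in range(2, n_alleles + 1):
        variant = list(sequence)
        chosen = rng.choice(len(candidates), size=min(n_variant_positions, len(candidates)),
                            replace=False)
        for ci in chosen:
            p = candidates[int(ci)]
            current = variant[p]
            variant[p] = str(rng.choice([b for b in "ACGT" if b != current]))
        panel.append(build((99, a, 1), variant))
    return panel
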