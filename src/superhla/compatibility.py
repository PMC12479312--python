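"""Donor-to-recipient immune compatibility modeling.

The matching rule is directional, host-versus-graft: a donor is compatible
with a recipient when, at every *retained* gene, the recipient carries every
allele the donor expresses — i.e. the donor's allele set (truncated to the
working field resolution) is a subset of the recipient's.  A graft presenting
no foreign class I allele offers no target for the recipient's CD8 T cells.
Homozygous donors present a single allele per gene and are therefore
systematically easier to place; knocking out a gene removes it from the
retained set and can only relax the rule.

Coverage of a donor panel over a recipient cohort is the fraction of
recipients matched by at least one donor; the coverage *curve* accumulates
donors in a seeded random order (the endpoint is order-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nomenclature import GENES, Cohort, Gene, Genotype, is_homozygous
from .registry import FrequencyTable

__all__ = [
    "CompatibilityConfig",
    "CoverageResult",
    "BaselineResult",
    "donor_matches",
    "cohort_coverage",
    "random_subset_baseline",
    "apply_knockout",
    "expected_triple_homozygotes",
]


@dataclass(frozen=True)
class CompatibilityConfig:
    """Matching rule: which genes are retained on the graft, at what resolution.

    ``retained_genes`` may be empty — a universal donor with every class I
    gene knocked out matches anyone.  ``direction`` is host-versus-graft
    (``"hvg"``) by default; ``"gvh"`` reverses the subset test and is provided
    for sensitivity analyses only.
    """

    retained_genes: frozenset[Gene] = frozenset(GENES)
    k: int = 3
    direction: str = "hvg"

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained_genes", frozenset(self.retained_genes))
        if self.k < 1:
            raise ValueError("field resolution k must be >= 1")
        if self.direction not in ("hvg", "gvh"):
            raise ValueError("direction must be 'hvg' or 'gvh'")


def donor_matches(donor: Genotype, recipient: Genotype, cfg: CompatibilityConfig) -> bool:
    """True iff the donor is compatible with the recipient under ``cfg``.

    Host-versus-graft: at every retained gene the donor's allele set must be a
    subset of the recipient's (the recipient sees no foreign allele).  With an
    empty retained set the condition is vacuous.
    """
    for gene in cfg.retained_genes:
        d = donor.allele_set(gene, cfg.k)
        r = recipient.allele_set(gene, cfg.k)
        ok = d <= r if cfg.direction == "hvg" else r <= d
        if not ok:
            return False
    return True


def apply_knockout(cfg_base: CompatibilityConfig, knockout_genes) -> CompatibilityConfig:
    """Remove knocked-out genes from the retained set (e.g. HLA-A/B knockout
    leaves the HLA-C-retained configuration)."""
    knockout = frozenset(knockout_genes)
    unknown = knockout - set(GENES)
    if unknown:
        raise ValueError(f"unknown genes in knockout set: {unknown}")
    return replace(cfg_base, retained_genes=cfg_base.retained_genes - knockout)


@dataclass(frozen=True)
class CoverageResult:
    """Coverage of a donor panel over a recipient cohort."""

    fraction_matched: float
    n_recipients: int
    n_donors: int
    #: per-donor marginal coverage: fraction of recipients each donor matches alone
    per_donor: dict[str, float]
    #: cumulative fraction matched after 1..n_donors donors, in the seeded order
    coverage_curve: list[float]
    donor_order: list[str]
    config: CompatibilityConfig
    seed: int | None


def _match_matrix(
    donors: Cohort, recipients: Cohort, cfg: CompatibilityConfig
) -> np.ndarray:
    """Boolean matrix M[d, r] = donor d matches recipient r.

    Indexed lookups keep this near-linear: recipients are grouped by the
    nonempty subsets of their per-gene allele sets, so each donor's matched
    set per gene is a single dictionary lookup.
    """
    n_r = len(recipients)
    if cfg.direction != "hvg":
        # rare analysis mode; fall back to the direct pairwise rule
        out = np.zeros((len(donors), n_r), dtype=bool)
        for i, d in enumerate(donors):
            for j, r in enumerate(recipients):
                out[i, j] = donor_matches(d, r, cfg)
        return out
    gene_index: dict[Gene, dict[frozenset, np.ndarray]] = {}
    for gene in cfg.retained_genes:
        index: dict[frozenset, np.ndarray] = {}
        for j, r in enumerate(recipients):
            alleles = r.allele_set(gene, cfg.k)
            subsets = [frozenset({a}) for a in alleles]
            if len(alleles) == 2:
                subsets.append(alleles)
            for s in subsets:
                index.setdefault(s, []).append(j)  # type: ignore[arg-type]
        gene_index[gene] = {
            s: np.asarray(js, dtype=np.int64) for s, js in index.items()
        }
    out = np.zeros((len(donors), n_r), dtype=bool)
    for i, d in enumerate(donors):
        matched = np.ones(n_r, dtype=bool)
        for gene in cfg.retained_genes:
            hits = np.zeros(n_r, dtype=bool)
            js = gene_index[gene].get(d.allele_set(gene, cfg.k))
            if js is not None:
                hits[js] = True
            matched &= hits
            if not matched.any():
                break
        out[i] = matched
    return out


def cohort_coverage(
    donors: Cohort,
    recipients: Cohort,
    cfg: CompatibilityConfig,
    seed: int | None = None,
    exclude_self: bool = False,
) -> CoverageResult:
    """Fraction of recipients matched by at least one donor, plus the seeded
    donor-accumulation curve.

    ``exclude_self`` drops donor-recipient pairs with identical ids (relevant
    when the donor panel is drawn from the recipient cohort itself).
    """
    if len(donors) == 0:
        raise ValueError("donor cohort is empty")
    if len(recipients) == 0:
        raise ValueError("recipient cohort is empty")
    matrix = _match_matrix(donors, recipients, cfg)
    if exclude_self:
        rec_ids = {r.individual_id: j for j, r in enumerate(recipients)}
        for i, d in enumerate(donors):
            j = rec_ids.get(d.individual_id)
            if j is not None:
                matrix[i, j] = False
    n_r = len(recipients)
    per_donor = {
        d.individual_id: float(matrix[i].sum()) / n_r for i, d in enumerate(donors)
    }
    fraction = float(matrix.any(axis=0).sum()) / n_r
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(donors))
    curve: list[float] = []
    cum = np.zeros(n_r, dtype=bool)
    for i in order:
        cum |= matrix[i]
        curve.append(float(cum.sum()) / n_r)
    return CoverageResult(
        fraction_matched=fraction,
        n_recipients=n_r,
        n_donors=len(donors),
        per_donor=per_donor,
        coverage_curve=curve,
        donor_order=[donors[int(i)].individual_id for i in order],
        config=cfg,
        seed=seed,
    )


@dataclass(frozen=True)
class BaselineResult:
    """Coverage distribution of random donor subsets of a cohort."""

    mean: float
    sd: float
    fractions: list[float]
    subset_size: int
    n_reps: int
    seed: int | None


def random_subset_baseline(
    cohort: Cohort,
    subset_size: int,
    cfg: CompatibilityConfig,
    n_reps: int,
    seed: int | None = None,
) -> BaselineResult:
    """Coverage of random ``subset_size``-donor panels drawn (without
    replacement) from ``cohort`` against the full cohort.

    This is the stochastic baseline a homozygous-donor panel is compared to:
    how much of the population would an arbitrary same-sized panel cover?
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if subset_size > len(cohort) or subset_size < 1:
        raise ValueError("subset_size must be in [1, cohort size]")
    matrix = _match_matrix(cohort, cohort, cfg)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    fractions = []
    for _ in range(n_reps):
        idx = rng.choice(n, size=subset_size, replace=False)
        covered = matrix[idx].any(axis=0)
        fractions.append(float(covered.sum()) / n)
    arr = np.array(fractions)
    return BaselineResult(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n_reps > 1 else 0.0,
        fractions=fractions,
        subset_size=subset_size,
        n_reps=n_reps,
        seed=seed,
    )


def expected_triple_homozygotes(
    freqs: dict[Gene, FrequencyTable],
    n: int,
    n_reps: int = 1000,
    seed: int | None = None,
    k: int = 3,
) -> tuple[float, float, float]:
    """Expected number of triple homozygotes in a cohort of ``n`` under
    independent-loci Hardy-Weinberg sampling from measured allele frequencies.

    Simulates ``n_reps`` cohorts and counts individuals homozygous at all
    three genes; returns ``(mean, sd, closed_form)`` where the closed form is
    ``n * prod_g sum_i p_{g,i}^2``.

    The simulation draws allele *indices* directly (equivalent to counting
    homozygotes in :func:`monte_carlo_population` output, but vectorised
    across replicates).
    """
    if n <= 0 or n_reps <= 0:
        raise ValueError("n and n_reps must be positive")
    rng = np.random.default_rng(seed)
    closed_form = float(n)
    for gene in GENES:
        table = freqs[gene]
        p = np.array([table[a] for a in table.alleles()], dtype=float)
        p = p / p.sum()
        closed_form *= float((p ** 2).sum())
    homo_all = np.ones((n_reps, n), dtype=bool)
    for gene in GENES:
        table = freqs[gene]
        p = np.array([table[a] for a in table.alleles()], dtype=float)
        p = p / p.sum()
        first = rng.choice(len(p), size=(n_reps, n), p=p)
        second = rng.choice(len(p), size=(n_reps, n), p=p)
        homo_all &= first == second
    counts = homo_all.sum(axis=1)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_reps > 1 else 0.0
    return mean, sd, closed_form


def triple_homozygotes(cohort: Cohort, k: int = 3) -> Cohort:
    """The sub-cohort homozygous at all three class I genes."""
    idx = [
        i for i, g in enumerate(cohort)
        if all(is_homozygous(g, gene, k) for gene in GENES)
    ]
    return cohort.subset(idx, label=f"{cohort.label}-triple-homozygous")


def double_homozygotes(cohort: Cohort, k: int = 3, exactly: bool = True) -> Cohort:
    """The sub-cohort homozygous at exactly (or at least) two genes."""
    idx = []
    for i, g in enumerate(cohort):
        n_homo = sum(is_homozygous(g, gene, k) for gene in GENES)
        if (n_homo == 2) if exactly else (n_homo >= 2):
            idx.append(i)
    return cohort.subset(idx, label=f"{cohort.label}-double-homozygous")
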