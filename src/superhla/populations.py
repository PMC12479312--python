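"""Cross-population comparison of HLA class I allele composition.

Two populations typed (or published) at compatible resolution are compared
three ways:

1. ordinary least-squares regression of one gene's allele frequencies on the
   other's, over the union of alleles (absent alleles at frequency 0);
2. Monte Carlo reconstruction of genotype cohorts from published per-gene
   allele frequencies (loci drawn independently — published tables carry no
   between-gene linkage information);
3. presence/absence one-hot encoding of genotypes, PCA, per-population
   centroids and Euclidean centroid distances.

One-hot encoding records carriage (at least one copy) of each allele, not
dosage, so homozygosity information is deliberately not retained; a dosage
mode exists for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .nomenclature import GENES, Allele, Cohort, Gene, Genotype, parse_allele
from .registry import FrequencyTable

__all__ = [
    "RegressionFit",
    "PopulationEmbedding",
    "regress_frequencies",
    "monte_carlo_population",
    "one_hot",
    "pca_centroids",
    "read_frequency_csv",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def regress_frequencies(f1: FrequencyTable, f2: FrequencyTable) -> RegressionFit:
    """OLS of ``f2`` frequencies on ``f1`` frequencies over the allele union.

    Alleles absent from one table are imputed frequency 0, so the support is
    the union, not the intersection.
    """
    if f1.gene is not f2.gene:
        raise ValueError(f"gene mismatch: {f1.gene.long_name} vs {f2.gene.long_name}")
    union = sorted(set(f1.entries) | set(f2.entries))
    if len(union) < 2:
        raise ValueError("need at least 2 allele support points for a regression")
    x = np.array([f1[a] for a in union])
    y = np.array([f2[a] for a in union])
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(union),
    )


def read_frequency_csv(path, gene: Gene, renormalize: bool = True,
                       n_individuals: int = 0) -> FrequencyTable:
    """Read a published allele-frequency table (CSV columns: allele, frequency)."""
    df = pd.read_csv(path)
    for col in ("allele", "frequency"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    freqs = {parse_allele(str(a)): float(f) for a, f in zip(df["allele"], df["frequency"])}
    return FrequencyTable.from_mapping(gene, freqs, n_individuals=n_individuals,
                                       renormalize=renormalize)


def monte_carlo_population(
    freqs: dict[Gene, FrequencyTable],
    n: int,
    seed: int | np.random.Generator,
    label: str = "simulated",
    id_prefix: str | None = None,
) -> Cohort:
    """Simulate ``n`` genotypes by drawing two alleles per gene i.i.d. from
    each gene's frequency table (independent loci, Hardy-Weinberg proportions).

    Deterministic given the seed.  Frequencies are renormalised defensively in
    case a published table does not sum exactly to 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    missing = [g.long_name for g in GENES if g not in freqs]
    if missing:
        raise ValueError(f"missing frequency tables for {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else f"{label}-"
    draws: dict[Gene, np.ndarray] = {}
    allele_lists: dict[Gene, list[Allele]] = {}
    for gene in GENES:
        table = freqs[gene]
        alleles = table.alleles()
        p = np.array([table[a] for a in alleles], dtype=float)
        p = p / p.sum()
        allele_lists[gene] = alleles
        draws[gene] = rng.choice(len(alleles), size=(n, 2), p=p)
    width = max(4, len(str(n)))
    genotypes = []
    for i in range(n):
        calls = {
            gene: (
                allele_lists[gene][draws[gene][i, 0]],
                allele_lists[gene][draws[gene][i, 1]],
            )
            for gene in GENES
        }
        genotypes.append(Genotype(individual_id=f"{prefix}{i:0{width}d}", calls=calls))
    return Cohort(genotypes, label=label)


def one_hot(
    cohorts: list[Cohort],
    k: int = 3,
    dosage: bool = False,
) -> tuple[np.ndarray, list[tuple[Gene, Allele]], list[str]]:
    """Encode genotypes as a binary (or dosage) matrix.

    One row per individual across all cohorts; one column per (gene, allele)
    over the union of alleles seen in any cohort, truncated to ``k`` fields.
    In presence/absence mode an entry is 1 iff the individual carries at least
    one copy; in dosage mode it is the copy number (0/1/2).

    Returns ``(matrix, legend, labels)`` where ``legend[j]`` names column j
    and ``labels[i]`` is the cohort label of row i.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    legend: list[tuple[Gene, Allele]] = []
    seen: set[tuple[Gene, Allele]] = set()
    for cohort in cohorts:
        for g in cohort:
            for gene in GENES:
                for allele in g.alleles_at(gene, k):
                    key = (gene, allele)
                    if key not in seen:
                        seen.add(key)
                        legend.append(key)
    legend.sort(key=lambda key: (key[0].value, key[1]))
    col_index = {key: j for j, key in enumerate(legend)}
    n_rows = sum(len(c) for c in cohorts)
    matrix = np.zeros((n_rows, len(legend)), dtype=np.int8)
    labels: list[str] = []
    i = 0
    for cohort in cohorts:
        for g in cohort:
            for gene in GENES:
                for allele in g.alleles_at(gene, k):
                    j = col_index[(gene, allele)]
                    if dosage:
                        matrix[i, j] += 1
                    else:
                        matrix[i, j] = 1
            labels.append(cohort.label)
            i += 1
    return matrix, legend, labels


@dataclass
class PopulationEmbedding:
    """PCA embedding of one-hot genotypes with per-population centroids."""

    coordinates: np.ndarray              # (n_individuals, n_components)
    labels: list[str]                    # row labels
    populations: list[str]               # distinct labels, first-appearance order
    centroids: np.ndarray                # (n_populations, n_components)
    distances: pd.DataFrame              # symmetric centroid distance matrix
    explained_variance_ratio: np.ndarray
    degenerate: bool = False

    def normalized_distances(self, pair: tuple[str, str]) -> pd.DataFrame:
        """Distances rescaled so that ``pair`` has distance 1.00 (relative units)."""
        ref = self.distances.loc[pair[0], pair[1]]
        if ref == 0:
            raise ValueError("reference pair has zero distance; cannot normalize")
        return self.distances / ref


def pca_centroids(
    matrix: np.ndarray,
    labels: list[str],
    n_components: int = 2,
) -> PopulationEmbedding:
    """PCA (mean-centering, no variance scaling) of a one-hot genotype matrix,
    with per-population centroids and Euclidean centroid distances.

    If the matrix has no variance at all (all rows identical) the embedding is
    flagged degenerate and every distance is 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows for a PCA")
    if len(labels) != matrix.shape[0]:
        raise ValueError("labels must match matrix rows")
    populations = list(dict.fromkeys(labels))
    degenerate = bool(np.allclose(matrix, matrix[0]))
    if degenerate:
        coords = np.zeros((matrix.shape[0], n_components))
        evr = np.zeros(n_components)
    else:
        n_components_eff = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
        pca = PCA(n_components=n_components_eff, svd_solver="full")
        coords = pca.fit_transform(matrix)
        if n_components_eff < n_components:
            coords = np.pad(coords, ((0, 0), (0, n_components - n_components_eff)))
        evr = np.pad(pca.explained_variance_ratio_,
                     (0, n_components - n_components_eff))
    label_arr = np.array(labels)
    centroids = np.vstack([coords[label_arr == p].mean(axis=0) for p in populations])
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    distances = pd.DataFrame(dist, index=populations, columns=populations)
    return PopulationEmbedding(
        coordinates=coords,
        labels=list(labels),
        populations=populations,
        centroids=centroids,
        distances=distances,
        explained_variance_ratio=evr,
        degenerate=degenerate,
    )
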