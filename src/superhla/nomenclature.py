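"""HLA class I nomenclature, genotypes and registry I/O.

The three classical class I loci (HLA-A, HLA-B, HLA-C) are named with the
IPD-IMGT/HLA colon-delimited convention, e.g. ``A*02:01:01``: field 1 is the
allele group, field 2 the protein, field 3 synonymous coding changes and
field 4 non-coding changes, optionally followed by an expression suffix
(N, L, S, Q, C, A).  Registries type donors at a given *field resolution*;
every downstream statistic in this package is parameterised by the number of
fields ``k`` at which two allele names are considered identical.
"""

from __future__ import annotations

import enum
import functools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "Gene",
    "GENES",
    "Allele",
    "Genotype",
    "Cohort",
    "AlleleParseError",
    "CohortFormatError",
    "parse_allele",
    "truncate_resolution",
    "is_homozygous",
    "read_cohort",
    "write_cohort",
]


class Gene(enum.Enum):
    """The three classical HLA class I loci."""

    A = "A"
    B = "B"
    C = "C"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"HLA-{self.value}"

    @property
    def long_name(self) -> str:
        return f"HLA-{self.value}"


#: Canonical locus order used everywhere (columns, iteration, sorting).
GENES: tuple[Gene, Gene, Gene] = (Gene.A, Gene.B, Gene.C)

_EXPRESSION_SUFFIXES = frozenset("NLSQCA")

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Za-z0-9]+)\*"
    r"(?P<fields>\d{1,4}(?::\d{1,4}){0,3})"
    r"(?P<suffix>[A-Z])?$"
)


class AlleleParseError(ValueError):
    """Raised when an allele name cannot be interpreted."""


class CohortFormatError(ValueError):
    """Raised when a registry table violates the expected layout."""


@functools.total_ordering
@dataclass(frozen=True, eq=True)
class Allele:
    """A parsed HLA allele name.

    Ordering is lexicographic on (gene, numeric fields, suffix), which matches
    the nomenclature sort order used in registry reports.  Suffixed alleles
    (e.g. null ``N`` variants) compare as distinct from unsuffixed ones.
    """

    gene: Gene
    fields: tuple[int, ...]
    suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.fields:
            raise AlleleParseError("an allele needs at least one field")
        if len(self.fields) > 4:
            raise AlleleParseError(f"too many fields in {self.fields!r}")
        if self.suffix is not None and self.suffix not in _EXPRESSION_SUFFIXES:
            raise AlleleParseError(f"unknown expression suffix {self.suffix!r}")
        object.__setattr__(self, "fields", tuple(int(f) for f in self.fields))

    @property
    def _sort_key(self) -> tuple[str, tuple[int, ...], str]:
        return (self.gene.value, self.fields, self.suffix or "")

    def __lt__(self, other: "Allele") -> bool:
        if not isinstance(other, Allele):
            return NotImplemented
        return self._sort_key < other._sort_key

    @property
    def resolution(self) -> int:
        """Number of typed fields."""
        return len(self.fields)

    @property
    def canonical_text(self) -> str:
        """Name with every field zero-padded to two digits, e.g. ``A*02:01:01``."""
        body = ":".join(f"{f:02d}" for f in self.fields)
        return f"{self.gene.value}*{body}{self.suffix or ''}"

    def __str__(self) -> str:
        return self.canonical_text


def parse_allele(text: str) -> Allele:
    """Parse an HLA class I allele name such as ``A*02:01:01`` or ``HLA-B*07:02``.

    Leading ``HLA-`` is stripped; fields are read as integers so leading zeros
    are not significant on input (they are restored on output).

    Raises
    ------
    AlleleParseError
        If the text is malformed, the locus is not A/B/C, or the suffix is not
        a recognised expression marker.
    """
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"malformed allele name: {text!r}")
    locus = m.group("locus")
    try:
        gene = Gene(locus)
    except ValueError:
        raise AlleleParseError(f"unknown locus {locus!r} in {text!r}") from None
    suffix = m.group("suffix")
    if suffix is not None and suffix not in _EXPRESSION_SUFFIXES:
        raise AlleleParseError(f"unknown expression suffix {suffix!r} in {text!r}")
    fields = tuple(int(f) for f in m.group("fields").split(":"))
    return Allele(gene=gene, fields=fields, suffix=suffix)


def truncate_resolution(allele: Allele, k: int) -> Allele:
    """Truncate an allele to its first ``k`` fields.

    The expression suffix is dropped whenever fields are removed, since it
    qualifies the full-resolution name.  ``k`` equal to the current resolution
    is the identity.

    Raises
    ------
    ValueError
        If ``k`` < 1 or the allele has fewer than ``k`` fields.
    """
    if k < 1:
        raise ValueError(f"field count must be >= 1, got {k}")
    if k > len(allele.fields):
        raise ValueError(
            f"{allele} has only {len(allele.fields)} fields; cannot report at {k}"
        )
    if k == len(allele.fields):
        return allele
    return Allele(gene=allele.gene, fields=allele.fields[:k], suffix=None)


@dataclass(frozen=True)
class Genotype:
    """One individual's unordered pair of allele calls at each class I locus.

    The two calls per gene carry no phase information: registry columns
    ``A_1``/``A_2`` are an arbitrary order, so calls are stored as a
    canonically sorted pair and compare order-insensitively.
    """

    individual_id: str
    calls: dict[Gene, tuple[Allele, Allele]]

    def __post_init__(self) -> None:
        if set(self.calls) != set(GENES):
            missing = [g.long_name for g in GENES if g not in self.calls]
            raise ValueError(f"genotype {self.individual_id!r} missing calls for {missing}")
        normalised: dict[Gene, tuple[Allele, Allele]] = {}
        for gene, pair in self.calls.items():
            if len(pair) != 2:
                raise ValueError(f"need exactly two calls at {gene.long_name}")
            a, b = pair
            for allele in (a, b):
                if allele.gene is not gene:
                    raise ValueError(
                        f"call {allele} filed under {gene.long_name} "
                        f"for {self.individual_id!r}"
                    )
            normalised[gene] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "calls", normalised)

    def alleles_at(self, gene: Gene, k: int | None = None) -> tuple[Allele, Allele]:
        """The (sorted) call pair at ``gene``, optionally truncated to ``k`` fields."""
        a, b = self.calls[gene]
        if k is not None:
            a, b = truncate_resolution(a, k), truncate_resolution(b, k)
        return (a, b) if a <= b else (b, a)

    def allele_set(self, gene: Gene, k: int | None = None) -> frozenset[Allele]:
        return frozenset(self.alleles_at(gene, k))


def is_homozygous(genotype: Genotype, gene: Gene, k: int) -> bool:
    """True iff both calls at ``gene`` agree after truncation to ``k`` fields."""
    a, b = genotype.alleles_at(gene, k)
    return a == b


@dataclass
class Cohort:
    """An ordered collection of genotyped individuals with unique ids."""

    genotypes: list[Genotype]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genotypes:
            if g.individual_id in seen:
                raise ValueError(f"duplicate individual id {g.individual_id!r}")
            seen.add(g.individual_id)

    def __len__(self) -> int:
        return len(self.genotypes)

    def __iter__(self) -> Iterator[Genotype]:
        return iter(self.genotypes)

    def __getitem__(self, i: int) -> Genotype:
        return self.genotypes[i]

    def subset(self, indices: Sequence[int], label: str = "") -> "Cohort":
        return Cohort([self.genotypes[i] for i in indices], label or self.label)


_REGISTRY_COLUMNS = ("id", "A_1", "A_2", "B_1", "B_2", "C_1", "C_2")


def _sep_for(path: Path, format_spec: str | None) -> str:
    if format_spec is not None:
        return {"csv": ",", "tsv": "\t"}[format_spec]
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cohort(path: str | Path, format_spec: str | None = None, label: str | None = None) -> Cohort:
    """Read a genotype registry table.

    Expects a header with columns ``id, A_1, A_2, B_1, B_2, C_1, C_2``; one
    row per individual, complete typing (no missing calls).  ``format_spec``
    may be ``"csv"`` or ``"tsv"``; by default the delimiter is inferred from
    the file extension.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, format_spec), dtype=str)
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")
    genotypes: list[Genotype] = []
    seen: set[str] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(df.columns, row))
        ind_id = rec["id"]
        if pd.isna(ind_id) or not str(ind_id).strip():
            raise CohortFormatError(f"{path}, row {row_number}: empty id")
        ind_id = str(ind_id).strip()
        if ind_id in seen:
            raise CohortFormatError(f"{path}, row {row_number}: duplicate id {ind_id!r}")
        seen.add(ind_id)
        calls: dict[Gene, tuple[Allele, Allele]] = {}
        for gene in GENES:
            pair = []
            for slot in (1, 2):
                col = f"{gene.value}_{slot}"
                text = rec[col]
                if pd.isna(text) or not str(text).strip():
                    raise CohortFormatError(
                        f"{path}, row {row_number}: missing call in column {col}"
                    )
                try:
                    allele = parse_allele(str(text))
                except AlleleParseError as err:
                    raise CohortFormatError(
                        f"{path}, row {row_number}, column {col}: {err}"
                    ) from err
                if allele.gene is not gene:
                    raise CohortFormatError(
                        f"{path}, row {row_number}, column {col}: "
                        f"{allele} is not an {gene.long_name} allele"
                    )
                pair.append(allele)
            calls[gene] = (pair[0], pair[1])
        genotypes.append(Genotype(individual_id=ind_id, calls=calls))
    return Cohort(genotypes, label=label if label is not None else path.stem)


def write_cohort(cohort: Cohort, path: str | Path, format_spec: str | None = None) -> None:
    """Write a cohort back to the registry table layout (round-trips with read_cohort)."""
    path = Path(path)
    rows = []
    for g in cohort:
        rec: dict[str, str] = {"id": g.individual_id}
        for gene in GENES:
            a, b = g.alleles_at(gene)
            rec[f"{gene.value}_1"] = a.canonical_text
            rec[f"{gene.value}_2"] = b.canonical_text
        rows.append(rec)
    df = pd.DataFrame(rows, columns=list(_REGISTRY_COLUMNS))
    df.to_csv(path, sep=_sep_for(path, format_spec), index=False)


def resolution_profile(cohort: Cohort) -> dict[str, set[int]]:
    """Distinct field resolutions seen per registry column (for validation reports)."""
    profile: dict[str, set[int]] = {}
    for gene in GENES:
        for slot in (1, 2):
            col = f"{gene.value}_{slot}"
            profile[col] = set()
    for g in cohort:
        for gene in GENES:
            a, b = g.alleles_at(gene)
            profile[f"{gene.value}_1"].add(a.resolution)
            profile[f"{gene.value}_2"].add(b.resolution)
    return profile
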