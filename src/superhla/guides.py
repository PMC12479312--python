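"""Cas9 guide-RNA design cascade for HLA class I genes.

The cascade mirrors how knockout guides are triaged for a single-span type I
membrane protein:

1. extract every SpCas9 site (20-nt protospacer + NGG PAM) on both strands of
   each allele's gene body (5'UTR through 3'UTR);
2. score each site's 30-nt context with the Rule Set 1 logistic on-target
   activity model;
3. annotate each site by its blunt-cut position (between protospacer
   positions 17 and 18, 3 bp 5' of the PAM): inside an exon, and if so,
   upstream of the first transmembrane-helix codon (the ectodomain) — only
   ectodomain cuts can abolish surface expression;
4. deduplicate sites across the allele panel on (protospacer, PAM) and report
   the nested counts gene body >= exon >= ectodomain >= high activity
   (score > 0.5);
5. optionally discard candidates whose protospacer+PAM occurs verbatim in any
   HLA-C allele, so HLA-A/HLA-B knockouts spare HLA-C.

Region membership is decided by the cut position, not protospacer overlap,
because the indel position governs where the frameshift lands; this is an
explicit convention and may differ from pipelines that use overlap.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .nomenclature import Allele, Gene, parse_allele

__all__ = [
    "AnnotatedGeneSequence",
    "GuideSite",
    "SiteScan",
    "CascadeCounts",
    "find_cas9_sites",
    "ruleset1_score",
    "protein_to_cds_coordinate",
    "annotate_site_regions",
    "design_guides",
    "unique_sites_across_alleles",
    "spare_hla_c_filter",
    "read_gene_panel",
    "write_gene_panel",
    "sites_to_frame",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotatedGeneSequence:
    """A plus-strand gene-body sequence (5'UTR..3'UTR) with exon/CDS/TM annotation.

    ``exons`` are 0-based half-open intervals on ``sequence``; the CDS is the
    exonic positions in ``[cds_start, cds_end)``.  ``tm_protein_span`` is the
    1-based inclusive residue interval of the transmembrane helix; when
    ``tm_includes_signal_peptide`` is False the span is on mature-protein
    numbering and ``signal_peptide_length`` residues are added to place it on
    the CDS translation.
    """

    allele: Allele
    sequence: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    tm_protein_span: tuple[int, int]
    tm_includes_signal_peptide: bool = True
    signal_peptide_length: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = [i for i, c in enumerate(seq) if c not in "ACGT"]
        if bad:
            shown = ", ".join(str(i) for i in bad[:10])
            raise ValueError(f"non-ACGT characters at position(s) {shown}")
        object.__setattr__(self, "exons", tuple((int(a), int(b)) for a, b in self.exons))
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end <= len(seq)):
                raise ValueError(f"exon ({start}, {end}) outside sequence")
            if start <= prev_end:
                raise ValueError("exons must be non-overlapping and ascending")
            prev_end = end
        if len(self.cds_positions()) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        tm_lo, tm_hi = self.tm_protein_span
        if not (1 <= tm_lo <= tm_hi):
            raise ValueError("transmembrane span must be 1-based and ordered")
        if self._tm_cds_residue(tm_hi) > self.protein_length:
            raise ValueError("transmembrane span outside protein")

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS nucleotides, in transcript order."""
        out = []
        for start, end in self.exons:
            lo, hi = max(start, self.cds_start), min(end, self.cds_end)
            out.extend(range(lo, hi))
        return out

    @property
    def protein_length(self) -> int:
        return len(self.cds_positions()) // 3

    def _tm_cds_residue(self, residue: int) -> int:
        """Map a TM-annotation residue number onto CDS-translation numbering."""
        offset = 0 if self.tm_includes_signal_peptide else self.signal_peptide_length
        return residue + offset

    def tm_first_cds_residue(self) -> int:
        return self._tm_cds_residue(self.tm_protein_span[0])

    def ectodomain_boundary(self) -> int:
        """Genomic position of the first nucleotide of the first TM codon.

        Cuts strictly upstream of this position (and inside an exon) land in
        the ectodomain-coding region.
        """
        codon = protein_to_cds_coordinate(self, self.tm_first_cds_residue())
        return codon[0][0]


def protein_to_cds_coordinate(
    seq: AnnotatedGeneSequence, residue_index: int
) -> list[tuple[int, int]]:
    """Genomic interval(s) of one codon, 0-based half-open, handling codons
    split across exon junctions (then two disjoint intervals are returned).

    ``residue_index`` is 1-based on the CDS translation.
    """
    if residue_index < 1 or residue_index > seq.protein_length:
        raise ValueError(
            f"residue {residue_index} outside protein of length {seq.protein_length}"
        )
    positions = seq.cds_positions()[3 * (residue_index - 1): 3 * residue_index]
    intervals: list[tuple[int, int]] = []
    for p in positions:
        if intervals and intervals[-1][1] == p:
            intervals[-1] = (intervals[-1][0], p + 1)
        else:
            intervals.append((p, p + 1))
    return intervals


@dataclass(frozen=True)
class GuideSite:
    """One SpCas9 target site on an annotated gene sequence.

    ``cut_pos`` is the plus-strand 0-based coordinate of the base immediately
    3' of the blunt cut (the cut falls between ``cut_pos - 1`` and
    ``cut_pos``), for both strands.  ``context30`` holds the protospacer at
    positions 5-24 and the PAM at 25-27 (1-based).
    """

    protospacer: str
    pam: str
    strand: str
    cut_pos: int
    context30: str
    score: float | None = None
    in_gene_body: bool = True
    in_exon: bool = False
    in_ectodomain: bool = False
    high_activity: bool = False
    allele: Allele | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.context30 and (
            len(self.context30) != 30
            or self.context30[4:24] != self.protospacer
            or self.context30[24:27] != self.pam
        ):
            raise ValueError("context30 inconsistent with protospacer/PAM")

    @property
    def key(self) -> tuple[str, str]:
        """Dedup key across alleles."""
        return (self.protospacer, self.pam)


@dataclass(frozen=True)
class SiteScan:
    """Result of site extraction: usable sites plus the tally of PAM hits whose
    30-mer scoring context would run off the sequence end."""

    sites: tuple[GuideSite, ...]
    n_context_dropped: int

    def __iter__(self) -> Iterator[GuideSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def find_cas9_sites(seq: AnnotatedGeneSequence | str) -> SiteScan:
    """Every 20-mer followed by an NGG PAM, on both strands.

    Minus-strand sites are reported with plus-strand cut coordinates via
    reverse complement.  Sites lacking the full 4+20+3+3 context window are
    dropped and counted in ``n_context_dropped``.
    """
    if isinstance(seq, AnnotatedGeneSequence):
        s = seq.sequence
        allele = seq.allele
    else:
        s = seq.upper()
        allele = None
        bad = [i for i, c in enumerate(s) if c not in "ACGT"]
        if bad:
            shown = ", ".join(str(i) for i in bad[:10])
            raise ValueError(f"non-ACGT characters at position(s) {shown}")
    n = len(s)
    if n < 30:
        raise ValueError("sequence shorter than one scoring context (30 nt)")
    sites: list[GuideSite] = []
    dropped = 0
    # plus strand: protospacer at [i, i+20), PAM at [i+20, i+23)
    for i in range(0, n - 22):
        if s[i + 21] == "G" and s[i + 22] == "G":
            if i - 4 < 0 or i + 26 > n:
                dropped += 1
                continue
            sites.append(
                GuideSite(
                    protospacer=s[i: i + 20],
                    pam=s[i + 20: i + 23],
                    strand="+",
                    cut_pos=i + 17,
                    context30=s[i - 4: i + 26],
                    allele=allele,
                )
            )
    # minus strand: scan the reverse complement the same way, map back
    rc = reverse_complement(s)
    for j in range(0, n - 22):
        if rc[j + 21] == "G" and rc[j + 22] == "G":
            if j - 4 < 0 or j + 26 > n:
                dropped += 1
                continue
            sites.append(
                GuideSite(
                    protospacer=rc[j: j + 20],
                    pam=rc[j + 20: j + 23],
                    strand="-",
                    cut_pos=n - j - 17,
                    context30=rc[j - 4: j + 26],
                    allele=allele,
                )
            )
    sites.sort(key=lambda g: (g.cut_pos, g.strand))
    return SiteScan(sites=tuple(sites), n_context_dropped=dropped)


# ---------------------------------------------------------------------------
# Rule Set 1 scoring

_RULESET1_SHA256 = "5abbee356bff9570fa86cc70db6c6572f0460e7180c9556d6e071d1522830905"


@dataclass(frozen=True)
class _Ruleset1Model:
    intercept: float
    gc_low: float
    gc_high: float
    features: tuple[tuple[int, str, float], ...]  # (0-based start, subsequence, weight)


_MODEL_CACHE: dict[str, _Ruleset1Model] = {}


def ruleset1_coefficients_path() -> Path:
    return Path(resources.files("superhla").joinpath("data/ruleset1_coefficients.csv"))


def load_ruleset1_model(path: str | Path | None = None, verify_checksum: bool = True) -> _Ruleset1Model:
    """Load (and cache) the Rule Set 1 coefficient asset.

    The bundled CSV is integrity-checked against a pinned sha256; a modified
    coefficient table would silently change every score, so a mismatch is an
    error rather than a warning.
    """
    path = Path(path) if path is not None else ruleset1_coefficients_path()
    cache_key = str(path)
    if cache_key in _MODEL_CACHE:
        return _MODEL_CACHE[cache_key]
    raw = path.read_bytes()
    if verify_checksum and path == ruleset1_coefficients_path():
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _RULESET1_SHA256:
            raise RuntimeError(
                "Rule Set 1 coefficient asset failed its integrity check "
                f"(sha256 {digest}); refusing to score"
            )
    intercept = gc_low = gc_high = None
    features: list[tuple[int, str, float]] = []
    rows = [
        r for r in csv.reader(raw.decode().splitlines())
        if r and not r[0].startswith("#")
    ]
    for row in rows[1:]:  # skip header
        kind, pos, subseq, weight = row
        w = float(weight)
        if kind == "intercept":
            intercept = w
        elif kind == "gc_low":
            gc_low = w
        elif kind == "gc_high":
            gc_high = w
        elif kind == "nt":
            features.append((int(pos) - 1, subseq, w))
        else:
            raise ValueError(f"unknown feature type {kind!r}")
    if intercept is None or gc_low is None or gc_high is None:
        raise ValueError("coefficient table missing intercept/GC terms")
    model = _Ruleset1Model(intercept, gc_low, gc_high, tuple(features))
    _MODEL_CACHE[cache_key] = model
    return model


def ruleset1_score(context30: str) -> float:
    """Rule Set 1 on-target activity score of a 30-nt context, in [0, 1].

    The model is a logistic over position-specific single/di-nucleotide
    indicators plus a protospacer GC-count penalty: one unit of weight
    ``gc_low`` per GC below 10, ``gc_high`` per GC above 10.
    """
    context30 = context30.upper()
    if len(context30) != 30:
        raise ValueError(f"scoring context must be 30 nt, got {len(context30)}")
    if any(c not in "ACGT" for c in context30):
        raise ValueError("scoring context must be ACGT only")
    model = load_ruleset1_model()
    total = model.intercept
    gc = context30[4:24].count("G") + context30[4:24].count("C")
    if gc < 10:
        total += (10 - gc) * model.gc_low
    elif gc > 10:
        total += (gc - 10) * model.gc_high
    for start, subseq, weight in model.features:
        if context30[start: start + len(subseq)] == subseq:
            total += weight
    return 1.0 / (1.0 + math.exp(-total))


def annotate_site_regions(site: GuideSite, seq: AnnotatedGeneSequence) -> GuideSite:
    """Fill the nested region flags from the cut position.

    ``in_exon`` iff the cut position falls inside an exon; ``in_ectodomain``
    additionally requires the cut to lie strictly upstream of the first
    transmembrane codon; ``high_activity`` additionally requires a Rule Set 1
    score above 0.5 (the site is scored here if it has none yet).
    """
    score = site.score
    if score is None and site.context30:
        score = ruleset1_score(site.context30)
    in_exon = any(start <= site.cut_pos < end for start, end in seq.exons)
    in_ectodomain = in_exon and site.cut_pos < seq.ectodomain_boundary()
    high = in_ectodomain and score is not None and score > 0.5
    return replace(
        site,
        score=score,
        in_exon=in_exon,
        in_ectodomain=in_ectodomain,
        high_activity=high,
        allele=seq.allele,
    )


def design_guides(seq: AnnotatedGeneSequence) -> SiteScan:
    """Extract, score and region-annotate every usable Cas9 site of one allele."""
    scan = find_cas9_sites(seq)
    annotated = tuple(annotate_site_regions(s, seq) for s in scan.sites)
    return SiteScan(sites=annotated, n_context_dropped=scan.n_context_dropped)


@dataclass(frozen=True)
class CascadeCounts:
    """Nested unique-site counts of the design cascade for one gene."""

    gene_body: int
    exon: int
    ectodomain: int
    high_activity: int

    def __post_init__(self) -> None:
        if not (self.gene_body >= self.exon >= self.ectodomain >= self.high_activity >= 0):
            raise ValueError("cascade counts must be nested")


def unique_sites_across_alleles(
    sites_per_allele: Mapping[Allele, Sequence[GuideSite]] | Sequence[Sequence[GuideSite]],
    gene: Gene | None = None,
) -> tuple[list[GuideSite], CascadeCounts]:
    """Deduplicate sites across an allele panel on (protospacer, PAM).

    A deduplicated site keeps the first occurrence's coordinates but OR-merges
    the region flags over all occurrences: a site counts for a stage if it
    qualifies on *any* allele carrying it (set-union semantics per stage).
    """
    if isinstance(sites_per_allele, Mapping):
        groups: Iterable[Sequence[GuideSite]] = sites_per_allele.values()
        if gene is not None:
            for allele in sites_per_allele:
                if allele.gene is not gene:
                    raise ValueError(f"{allele} does not belong to {gene.long_name}")
    else:
        groups = sites_per_allele
    merged: dict[tuple[str, str], GuideSite] = {}
    for sites in groups:
        for site in sites:
            prev = merged.get(site.key)
            if prev is None:
                merged[site.key] = site
            else:
                merged[site.key] = replace(
                    prev,
                    in_exon=prev.in_exon or site.in_exon,
                    in_ectodomain=prev.in_ectodomain or site.in_ectodomain,
                    high_activity=prev.high_activity or site.high_activity,
                )
    unique = list(merged.values())
    counts = CascadeCounts(
        gene_body=len(unique),
        exon=sum(s.in_exon for s in unique),
        ectodomain=sum(s.in_ectodomain for s in unique),
        high_activity=sum(s.high_activity for s in unique),
    )
    return unique, counts


def spare_hla_c_filter(
    candidates: Sequence[GuideSite],
    hla_c_sequences: Sequence[AnnotatedGeneSequence | str],
) -> list[GuideSite]:
    """Drop candidates whose protospacer+PAM occurs verbatim (either strand)
    in any supplied HLA-C allele sequence, so the knockout spares HLA-C."""
    haystacks = []
    for s in hla_c_sequences:
        text = s.sequence if isinstance(s, AnnotatedGeneSequence) else s.upper()
        haystacks.append(text)
        haystacks.append(reverse_complement(text))
    kept = []
    for site in candidates:
        target = site.protospacer + site.pam
        if not any(target in h for h in haystacks):
            kept.append(site)
    return kept


# ---------------------------------------------------------------------------
# File I/O

def read_gene_panel(
    fasta_path: str | Path,
    exons_path: str | Path,
    tm_path: str | Path,
) -> list[AnnotatedGeneSequence]:
    """Read an allele panel: FASTA gene sequences + exon TSV + TM-span TSV.

    FASTA headers are parsed leniently: the first whitespace-separated token
    containing ``*`` is taken as the allele name (IPD-IMGT/HLA style
    ``>HLA:HLA00001 A*01:01:01:01 3503 bp`` works, as does a bare name).

    The exon TSV needs columns ``allele, start, end, exon_index`` (0-based
    half-open) plus ``cds_start, cds_end`` (repeated on each of an allele's
    rows).  The TM TSV needs ``allele_or_gene, tm_start_res, tm_end_res,
    includes_signal_peptide`` and optionally ``signal_peptide_length``; a row
    keyed by a bare gene name (``A``/``HLA-A``) acts as that gene's consensus.
    """
    exons_df = pd.read_csv(exons_path, sep="\t", dtype={"allele": str})
    tm_df = pd.read_csv(tm_path, sep="\t", dtype={"allele_or_gene": str})

    exon_map: dict[str, dict] = {}
    for name, grp in exons_df.groupby("allele"):
        grp = grp.sort_values("exon_index")
        exon_map[str(name)] = {
            "exons": tuple(zip(grp["start"].astype(int), grp["end"].astype(int))),
            "cds_start": int(grp["cds_start"].iloc[0]),
            "cds_end": int(grp["cds_end"].iloc[0]),
        }

    def tm_for(allele: Allele) -> dict:
        keys = [allele.canonical_text, f"HLA-{allele.gene.value}", allele.gene.value]
        for key in keys:
            rows = tm_df[tm_df["allele_or_gene"] == key]
            if len(rows):
                row = rows.iloc[0]
                includes = str(row["includes_signal_peptide"]).strip().lower() in {
                    "yes", "true", "1"
                }
                sp_len = int(row["signal_peptide_length"]) if "signal_peptide_length" in rows.columns and not pd.isna(row.get("signal_peptide_length")) else 0
                if not includes and sp_len == 0:
                    raise ValueError(
                        f"TM span for {key} is on mature numbering but no "
                        "signal_peptide_length was given"
                    )
                return {
                    "tm_protein_span": (int(row["tm_start_res"]), int(row["tm_end_res"])),
                    "tm_includes_signal_peptide": includes,
                    "signal_peptide_length": sp_len,
                }
        raise ValueError(f"no transmembrane annotation for {allele}")

    panel = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        header = f"{record.id} {record.description}"
        name = next((tok for tok in header.split() if "*" in tok), None)
        if name is None:
            raise ValueError(f"cannot find an allele name in FASTA header {header!r}")
        allele = parse_allele(name)
        if allele.canonical_text not in exon_map:
            raise ValueError(f"no exon annotation for {allele}")
        ann = exon_map[allele.canonical_text]
        panel.append(
            AnnotatedGeneSequence(
                allele=allele,
                sequence=str(record.seq),
                exons=ann["exons"],
                cds_start=ann["cds_start"],
                cds_end=ann["cds_end"],
                **tm_for(allele),
            )
        )
    return panel


def write_gene_panel(
    panel: Sequence[AnnotatedGeneSequence],
    fasta_path: str | Path,
    exons_path: str | Path,
    tm_path: str | Path,
) -> None:
    """Write a panel in the formats read_gene_panel expects (round-trips)."""
    with open(fasta_path, "w") as fh:
        for g in panel:
            fh.write(f">{g.allele.canonical_text} {len(g.sequence)} bp\n")
            for i in range(0, len(g.sequence), 60):
                fh.write(g.sequence[i: i + 60] + "\n")
    exon_rows = []
    for g in panel:
        for idx, (start, end) in enumerate(g.exons, start=1):
            exon_rows.append(
                {
                    "allele": g.allele.canonical_text,
                    "start": start,
                    "end": end,
                    "exon_index": idx,
                    "cds_start": g.cds_start,
                    "cds_end": g.cds_end,
                }
            )
    pd.DataFrame(exon_rows).to_csv(exons_path, sep="\t", index=False)
    tm_rows = [
        {
            "allele_or_gene": g.allele.canonical_text,
            "tm_start_res": g.tm_protein_span[0],
            "tm_end_res": g.tm_protein_span[1],
            "includes_signal_peptide": "yes" if g.tm_includes_signal_peptide else "no",
            "signal_peptide_length": g.signal_peptide_length,
        }
        for g in panel
    ]
    pd.DataFrame(tm_rows).to_csv(tm_path, sep="\t", index=False)


def sites_to_frame(sites: Sequence[GuideSite]) -> pd.DataFrame:
    """Human-facing site table: 1-based cut coordinates, flags as columns."""
    rows = [
        {
            "allele": s.allele.canonical_text if s.allele else "",
            "cut_pos": s.cut_pos + 1,
            "strand": s.strand,
            "protospacer": s.protospacer,
            "pam": s.pam,
            "context30": s.context30,
            "score": s.score,
            "in_exon": s.in_exon,
            "in_ectodomain": s.in_ectodomain,
            "high_activity": s.high_activity,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "allele", "cut_pos", "strand", "protospacer", "pam",
            "context30", "score", "in_exon", "in_ectodomain", "high_activity",
        ],
    )
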