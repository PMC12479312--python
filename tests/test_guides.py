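"""Cas9 site extraction, Rule Set 1 scoring, coordinate mapping and the cascade."""

import csv
import math
import re

import numpy as np
import pytest

from superhla import (
    AnnotatedGeneSequence,
    Gene,
    design_guides,
    find_cas9_sites,
    parse_allele,
    protein_to_cds_coordinate,
    ruleset1_score,
    spare_hla_c_filter,
    toy_gene_builder,
    unique_sites_across_alleles,
)
from superhla.guides import (
    GuideSite,
    load_ruleset1_model,
    read_gene_panel,
    reverse_complement,
    ruleset1_coefficients_path,
    sites_to_frame,
    write_gene_panel,
)


def _random_seq(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def _brute_force_sites(seq):
    """Regex-based two-strand oracle: (strand, protospacer, pam, cut_pos)."""
    found = set()
    for m in re.finditer(r"(?=([ACGT]{20})([ACGT]GG))", seq):
        i = m.start()
        if i - 4 >= 0 and i + 26 <= len(seq):
            found.add(("+", m.group(1), m.group(2), i + 17))
    rc = reverse_complement(seq)
    for m in re.finditer(r"(?=([ACGT]{20})([ACGT]GG))", rc):
        j = m.start()
        if j - 4 >= 0 and j + 26 <= len(rc):
            found.add(("-", m.group(1), m.group(2), len(seq) - j - 17))
    return found


class TestSiteExtraction:
    def test_no_gg_no_sites(self):
        seq = "ATATATATAT" * 10  # no GG or CC dinucleotide anywhere
        assert len(find_cas9_sites(seq)) == 0

    def test_constructed_single_plus_strand_site(self):
        rng = np.random.default_rng(0)
        protospacer = "ATCTTCTCATCATCTACTCA"  # no GG/CC
        seq = "TATA" + protospacer + "AGG" + "TAT"
        scan = find_cas9_sites(seq)
        assert len(scan) == 1
        (site,) = scan
        assert site.strand == "+"
        assert site.protospacer == protospacer
        assert site.pam == "AGG"
        assert site.cut_pos == 4 + 17
        assert site.context30 == seq

    def test_context30_invariant(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(500, rng)
        for site in find_cas9_sites(seq):
            assert len(site.context30) == 30
            assert site.context30[4:24] == site.protospacer
            assert site.context30[24:27] == site.pam
            assert site.pam[1:] == "GG"

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            seq = _random_seq(1000, rng)
            got = {
                (s.strand, s.protospacer, s.pam, s.cut_pos)
                for s in find_cas9_sites(seq)
            }
            assert got == _brute_force_sites(seq)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = _random_seq(800, rng)
            assert len(find_cas9_sites(seq)) == len(
                find_cas9_sites(reverse_complement(seq))
            )

    def test_context_dropped_sites_are_counted(self):
        protospacer = "ATCTTCTCATCATCTACTCA"
        seq = protospacer + "AGG" + "TATATAT"  # PAM ok but no 4-nt upstream context
        scan = find_cas9_sites(seq)
        assert len(scan) == 0
        assert scan.n_context_dropped == 1

    def test_non_acgt_rejected_with_positions(self):
        with pytest.raises(ValueError, match="position"):
            find_cas9_sites("ACGT" * 10 + "N" + "ACGT" * 10)


def _oracle_score(context30):
    """Independent straight-line re-evaluation of the coefficient CSV."""
    rows = [
        r for r in csv.reader(ruleset1_coefficients_path().read_text().splitlines())
        if r and not r[0].startswith("#")
    ][1:]
    total = 0.0
    gc = sum(context30[i] in "GC" for i in range(4, 24))
    for kind, pos, subseq, weight in rows:
        w = float(weight)
        if kind == "intercept":
            total += w
        elif kind == "gc_low":
            total += w * (10 - gc) if gc < 10 else 0.0
        elif kind == "gc_high":
            total += w * (gc - 10) if gc > 10 else 0.0
        else:
            start = int(pos) - 1
            if context30[start: start + len(subseq)] == subseq:
                total += w
    return 1.0 / (1.0 + math.exp(-total))


class TestRuleset1:
    def test_scores_bounded_and_deterministic(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            ctx = _random_seq(30, rng)
            s = ruleset1_score(ctx)
            assert 0.0 < s < 1.0
            assert ruleset1_score(ctx) == s

    def test_agrees_with_independent_feature_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ctx = _random_seq(30, rng)
            assert abs(ruleset1_score(ctx) - _oracle_score(ctx)) < 1e-9

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ruleset1_score("ACGT" * 5)
        with pytest.raises(ValueError):
            ruleset1_score("N" * 30)

    def test_checksum_guard(self, tmp_path, monkeypatch):
        import superhla.guides as guides_mod

        tampered = tmp_path / "ruleset1_coefficients.csv"
        tampered.write_text(ruleset1_coefficients_path().read_text().replace(
            "0.59763615", "0.99999999"
        ))
        monkeypatch.setattr(guides_mod, "ruleset1_coefficients_path", lambda: tampered)
        guides_mod._MODEL_CACHE.clear()
        try:
            with pytest.raises(RuntimeError, match="integrity"):
                guides_mod.load_ruleset1_model()
        finally:
            guides_mod._MODEL_CACHE.clear()

    def test_score_depends_only_on_context(self):
        """Moving a site without changing its 30-mer leaves the score unchanged."""
        ctx = "TATA" + "ATCTTCTCATCATCTACTCA" + "AGG" + "TAT"
        s1 = find_cas9_sites(ctx)
        s2 = find_cas9_sites("ACAC" * 5 + ctx)  # shifted genomic location
        score1 = ruleset1_score(s1.sites[0].context30)
        shifted = [x for x in s2 if x.context30 == ctx]
        assert shifted and ruleset1_score(shifted[0].context30) == score1


@pytest.fixture(scope="module")
def toy_panel():
    return toy_gene_builder(n_alleles=4, seed=17)


@pytest.fixture(scope="module")
def toy_gene(toy_panel):
    return toy_panel[0]


class TestCodonMapping:
    def test_first_residue_is_first_cds_codon(self, toy_gene):
        ivs = protein_to_cds_coordinate(toy_gene, 1)
        positions = [p for a, b in ivs for p in range(a, b)]
        assert positions == toy_gene.cds_positions()[:3]

    def test_junction_codon_in_constructed_two_exon_gene(self):
        # exon1 carries 4 coding nt, so residue 2 splits 1|2 across the junction
        seq = "AAATGCA" + "GTGTGTGTGT" + "ACTGACTGAAA" + ("ACGT" * 8)
        gene = AnnotatedGeneSequence(
            allele=parse_allele("A*99:01"),
            sequence=seq,
            exons=((0, 7), (17, 28)),
            cds_start=3,
            cds_end=25,
            tm_protein_span=(1, 2),
        )
        ivs = protein_to_cds_coordinate(gene, 2)
        assert len(ivs) == 2
        assert sum(b - a for a, b in ivs) == 3
        assert ivs[0][1] == 7 and ivs[1][0] == 17

    def test_codons_tile_the_cds_exactly_once(self, toy_gene):
        tiled = [
            p
            for r in range(1, toy_gene.protein_length + 1)
            for a, b in protein_to_cds_coordinate(toy_gene, r)
            for p in range(a, b)
        ]
        assert tiled == toy_gene.cds_positions()

    def test_out_of_range_residue(self, toy_gene):
        with pytest.raises(ValueError):
            protein_to_cds_coordinate(toy_gene, 0)
        with pytest.raises(ValueError):
            protein_to_cds_coordinate(toy_gene, toy_gene.protein_length + 1)


class TestRegionAnnotation:
    def test_flags_nest(self, toy_gene):
        for site in design_guides(toy_gene):
            if site.high_activity:
                assert site.in_ectodomain
            if site.in_ectodomain:
                assert site.in_exon
            assert site.in_gene_body

    def test_intronic_cut_has_no_flags(self, toy_gene):
        exon_positions = {
            p for start, end in toy_gene.exons for p in range(start, end)
        }
        intronic = [
            s for s in design_guides(toy_gene) if s.cut_pos not in exon_positions
        ]
        assert intronic  # toy gene has introns with PAMs
        for s in intronic:
            assert not s.in_exon and not s.in_ectodomain and not s.high_activity

    def test_ectodomain_boundary_splits_exonic_cuts(self, toy_gene):
        boundary = toy_gene.ectodomain_boundary()
        for s in design_guides(toy_gene):
            if s.in_exon:
                assert s.in_ectodomain == (s.cut_pos < boundary)

    def test_cut_in_tm_codons_is_not_ectodomain(self, toy_gene):
        boundary = toy_gene.ectodomain_boundary()
        tm_sites = [
            s for s in design_guides(toy_gene)
            if s.in_exon and boundary <= s.cut_pos < boundary + 60
        ]
        assert tm_sites
        assert not any(s.in_ectodomain for s in tm_sites)

    def test_high_activity_threshold(self, toy_gene):
        for s in design_guides(toy_gene):
            assert s.high_activity == (s.in_ectodomain and s.score > 0.5)


class TestCascade:
    def test_identical_alleles_dedup_to_single_allele_counts(self, toy_gene):
        sites = list(design_guides(toy_gene).sites)
        _, single = unique_sites_across_alleles([sites])
        _, double = unique_sites_across_alleles([sites, sites])
        assert single == double

    def test_disjoint_sequences_are_additive(self):
        a = toy_gene_builder(n_alleles=1, seed=1)[0]
        b = toy_gene_builder(n_alleles=1, seed=2)[0]
        sa = list(design_guides(a).sites)
        sb = list(design_guides(b).sites)
        _, ca = unique_sites_across_alleles([sa])
        _, cb = unique_sites_across_alleles([sb])
        _, cab = unique_sites_across_alleles([sa, sb])
        shared = {s.key for s in sa} & {s.key for s in sb}
        assert cab.gene_body == ca.gene_body + cb.gene_body - len(shared)

    def test_counts_match_set_union_oracle(self, toy_panel):
        per_allele = {g.allele: list(design_guides(g).sites) for g in toy_panel}
        _, counts = unique_sites_across_alleles(per_allele)
        stages = {"gene_body": set(), "exon": set(), "ectodomain": set(), "high_activity": set()}
        for sites in per_allele.values():
            for s in sites:
                stages["gene_body"].add(s.key)
                if s.in_exon:
                    stages["exon"].add(s.key)
                if s.in_ectodomain:
                    stages["ectodomain"].add(s.key)
                if s.high_activity:
                    stages["high_activity"].add(s.key)
        assert counts.gene_body == len(stages["gene_body"])
        assert counts.exon == len(stages["exon"])
        assert counts.ectodomain == len(stages["ectodomain"])
        assert counts.high_activity == len(stages["high_activity"])
        assert (
            counts.gene_body >= counts.exon >= counts.ectodomain >= counts.high_activity
        )

    def test_dedup_idempotent(self, toy_panel):
        per_allele = [list(design_guides(g).sites) for g in toy_panel]
        once, c1 = unique_sites_across_alleles(per_allele)
        twice, c2 = unique_sites_across_alleles([once])
        assert c1 == c2
        assert {s.key for s in once} == {s.key for s in twice}

    def test_gene_mixing_rejected(self, toy_panel):
        per_allele = {g.allele: list(design_guides(g).sites) for g in toy_panel}
        with pytest.raises(ValueError):
            unique_sites_across_alleles(per_allele, gene=Gene.B)


class TestHlaCSparing:
    def test_planted_candidate_removed(self, toy_gene):
        sites = list(design_guides(toy_gene).sites)
        planted, other = sites[0], sites[1]
        rng = np.random.default_rng(6)
        decoy = (
            _random_seq(40, rng) + planted.protospacer + planted.pam + _random_seq(40, rng)
        )
        kept = spare_hla_c_filter([planted, other], [decoy])
        assert planted not in kept
        # reverse-complement occurrence is also a hit
        decoy_rc = reverse_complement(decoy)
        kept_rc = spare_hla_c_filter([planted, other], [decoy_rc])
        assert planted not in kept_rc

    def test_survivors_match_substring_oracle(self, toy_panel):
        c_gene = toy_gene_builder(gene=Gene.C, n_alleles=2, seed=33)
        candidates = [s for g in toy_panel[:2] for s in design_guides(g).sites]
        kept = spare_hla_c_filter(candidates, c_gene)
        haystack = [g.sequence for g in c_gene] + [
            reverse_complement(g.sequence) for g in c_gene
        ]
        for s in candidates:
            hit = any(s.protospacer + s.pam in h for h in haystack)
            assert (s in kept) == (not hit)


class TestPanelIO:
    def test_round_trip(self, toy_panel, tmp_path):
        fa, ex, tm = (tmp_path / "p.fa", tmp_path / "p_exons.tsv", tmp_path / "p_tm.tsv")
        write_gene_panel(toy_panel, fa, ex, tm)
        back = read_gene_panel(fa, ex, tm)
        assert len(back) == len(toy_panel)
        for orig, rt in zip(toy_panel, back):
            assert rt.allele == orig.allele
            assert rt.sequence == orig.sequence
            assert rt.exons == orig.exons
            assert (rt.cds_start, rt.cds_end) == (orig.cds_start, orig.cds_end)
            assert rt.tm_protein_span == orig.tm_protein_span

    def test_lenient_fasta_headers(self, toy_panel, tmp_path):
        fa, ex, tm = (tmp_path / "p.fa", tmp_path / "p_exons.tsv", tmp_path / "p_tm.tsv")
        write_gene_panel(toy_panel[:1], fa, ex, tm)
        # rewrite header in IPD-IMGT/HLA style
        lines = fa.read_text().splitlines()
        lines[0] = f">HLA:HLA00001 {toy_panel[0].allele.canonical_text} 3503 bp"
        fa.write_text("\n".join(lines) + "\n")
        back = read_gene_panel(fa, ex, tm)
        assert back[0].allele == toy_panel[0].allele

    def test_site_table_is_one_based(self, toy_gene):
        sites = list(design_guides(toy_gene).sites)[:5]
        df = sites_to_frame(sites)
        assert list(df["cut_pos"]) == [s.cut_pos + 1 for s in sites]


def test_guide_site_validation():
    with pytest.raises(ValueError, match="PAM"):
        GuideSite(protospacer="A" * 20, pam="ATT", strand="+", cut_pos=0, context30="")
    with pytest.raises(ValueError):
        GuideSite(protospacer="A" * 19, pam="AGG", strand="+", cut_pos=0, context30="")
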