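# superhla

Analysis toolkit for **HLA class I "superdonor" discovery** in genotyped donor
registries: allele-frequency and homozygosity statistics, Hardy–Weinberg
equilibrium testing, cross-population comparison, donor→recipient immune
compatibility modeling under natural and gene-edited configurations, and a
Cas9 guide-RNA design cascade for *HLA-A*/*HLA-B*/*HLA-C*.

It is written for immunogenetics and regenerative-medicine groups who work
with registry tables of class I genotypes (one row per individual, two allele
calls per gene at two- or three-field resolution) and want to ask: *which
donors cover how much of a population, and how much more would they cover
after HLA knockout?*

## The model

**Homozygosity and frequencies.** With `n` individuals each contributing two
allele calls per gene, the frequency of allele *a* is `count(a) / 2n`.  An
individual is homozygous at a gene when both calls agree after truncation to
`k` name fields (default `k = 3`).  Per-gene, pairwise and triple homozygote
counts use *at-least* semantics, and inclusion–exclusion converts them into
union/exclusive tallies.

**Hardy–Weinberg.** For a gene with `m` observed alleles at frequencies
`p_i`, expected genotype counts are `n·p_i²` (homozygotes) and `2n·p_i·p_j`
(heterozygotes); the test statistic is `χ² = Σ (O−E)²/E` over genotype
classes observed at least 5 times, with `df = m(m+1)/2 − m`.  When rare
classes are dropped the result carries an explicit approximation caveat.

**Compatibility.** Matching is directional (host-versus-graft): donor `D`
fits recipient `R` under retained-gene set `G` iff for every gene `g ∈ G`
the donor's allele set is contained in the recipient's,
`alleles(D, g) ⊆ alleles(R, g)` — the graft presents no foreign class I
allele.  Triple homozygotes ("superdonors") present one allele per gene and
are systematically easier to place; knocking genes out (e.g. the
*HLA-C*-retained configuration, `G = {C}`) removes constraints and can only
increase coverage.  Coverage of a donor panel is the fraction of recipients
matched by ≥ 1 donor, with a seeded random donor-accumulation curve and
random-subset baselines.  The expected number of triple homozygotes under
random mating is `n · Π_g Σ_i p_{g,i}²`, checked by simulation.

**Guide design.** For each allele gene-body sequence (5′UTR→3′UTR), every
20-nt protospacer followed by an NGG PAM is extracted on both strands, its
30-nt context scored with the published Rule Set 1 logistic on-target model
(coefficients bundled and checksum-verified), and the blunt-cut position
(between protospacer positions 17/18) classified as exonic / ectodomain
(upstream of the first transmembrane codon) / high-activity (score > 0.5).
Sites are deduplicated across alleles on (protospacer, PAM), and candidates
occurring verbatim in any *HLA-C* sequence can be filtered out so an
*HLA-A*/*HLA-B* knockout spares *HLA-C*.

**Synthetic data.** All stages run without downloads: registries are sampled
from a haplotype pool with a whole-haplotype autozygosity parameter `F`
(with probability `F` an individual carries two copies of one haplotype),
giving triple-homozygote probability `F + (1−F)·Σw²` and a method-of-moments
estimator for `F`; toy multi-exon genes with a CDS and TM span exercise the
guide cascade.

## Worked example

`examples/04_compatibility_model.py` samples a 2,000-donor synthetic
registry (demo haplotype pool, `F = 0.02`) and runs the compatibility model:

```
189 of 2000 individuals are triple homozygous.
Superdonor coverage, natural configuration:   97.70%
Superdonor coverage, HLA-C retained (A/B KO): 97.70%
Random 189-donor panels cover 81.85% +/- 4.91% — the stochastic baseline the
homozygous panel is compared against.

Under independent-loci Hardy-Weinberg sampling from the measured allele
frequencies, 5.22 +/- 2.27 triple homozygotes are expected (closed form
5.15); the observed 189 reflects the pool's haplotype structure and
autozygosity.
```

The first lines show the superdonor panel's population coverage against the
whole registry, under full retention and after modeling an *HLA-A*/*HLA-B*
double knockout; the baseline line shows what an arbitrary panel of the same
size would achieve; the last line contrasts the observed triple-homozygote
count with its random-mating expectation — the gap is the haplotype-sharing
signal the autozygosity model captures.  The other scripts in `examples/`
cover registry statistics, HWE testing, population comparison by one-hot PCA,
and the guide cascade.

A thin CLI mirrors the library (`superhla validate|freq|homozygotes|hwe|
simulate-pop|pca|match|baseline|guides|synth`); run `superhla --help`.

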