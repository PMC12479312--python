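# Methods

This note records the models, conventions and numerical choices behind
`superhla`, the reasoning where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real registry data.

## Nomenclature and resolution

Alleles are parsed from the IPD-IMGT/HLA colon-delimited convention
(`A*02:01:01`, optionally `HLA-`-prefixed, up to four numeric fields plus an
expression suffix N/L/S/Q/C/A).  Internally fields are integers; rendering
zero-pads every field to two digits.  All statistics are parameterised by a
field resolution `k` (default 3, matching third-field registries; `k = 2`
serves protein-level registries).  Truncation drops the expression suffix,
since the suffix qualifies the full-resolution name; suffixed alleles compare
as distinct from unsuffixed ones at full resolution.  Call pairs are stored
unordered — registry columns `A_1/A_2` carry no phase information.

Homozygosity is name equality at resolution `k`.  Registry typing chemistry
concentrates on exons 2–3, so third-field name equality is the operational
definition of coding-sequence homozygosity here; identity outside the typed
region is not verified by the data and not claimed.

## Homozygosity accounting

Per-gene, pairwise and triple homozygote counts use *at-least* semantics (a
triple homozygote counts in every smaller tally), matching how proportional
Euler diagrams are drawn.  Inclusion–exclusion then gives

    at_least_one = Σ per_gene − Σ per_pair + triple
    exactly_two  = Σ per_pair − 3·triple

Both derived counts are validated non-negative and `at_least_one ≤ n`;
violations indicate inconsistent inputs and raise.

Only fully homozygous individuals have an unambiguous three-locus haplotype
without statistical phasing, so the haplotype tally is restricted to them;
EM-based phasing of heterozygotes is deliberately out of scope.

## Hardy–Weinberg test

The test is the classical multi-allele χ²: allele frequencies estimated by
call counting over all observed genotypes (not ML under HWE — with complete
genotype data the two coincide), expected counts `n·p_i²` / `2n·p_i·p_j`,
`df = m(m+1)/2 − m` for `m` observed alleles.  Genotype classes observed
fewer than `min_count = 5` times are excluded from the χ² sum because the
asymptotic approximation is unreliable for rare classes.  Two deliberate
consequences:

- expected counts are **not** re-normalised after filtering, and `df` keeps
  the full formula.  This reproduces the filtering procedure as practised,
  but when classes are dropped the χ² reference distribution is only
  approximate; the result therefore carries `df_filter_mismatch = True` and
  the number of dropped classes, and `min_count = 0` recovers the exact
  textbook test (property-tested against an independent implementation).
- p-values are reported without multiple-testing correction; the caller sees
  `df`, the retained-class count and the caveat flag and can judge.

The type-I calibration check uses a pool designed so the approximation is
exact: three equifrequent alleles per gene (27-haplotype product pool), where
at n = 500 every genotype-class expectation is ≥ 55 and the filter never
engages.  500 null registries give a rejection rate inside the 99% binomial
interval around α = 0.05.  This verifies the machinery, not the behaviour of
the filtered test on highly polymorphic genes, where dropped classes make
the test conservative (the `F = 0.5` power check shows gross homozygote
excess is still detected with power > 0.9 at n = 2,000).

## Population comparison

Frequency regression is OLS (`y ~ mx + c`) over the **union** of alleles,
absent alleles imputed frequency 0 — using the intersection would discard
exactly the composition differences of interest.

Monte Carlo cohorts are reconstructed from per-gene frequency tables by
drawing two alleles per gene i.i.d. (independent loci, Hardy–Weinberg
proportions).  Published frequency tables carry no between-gene linkage, so
this is the only reconstruction they support; simulated cohorts therefore
*understate* haplotype structure, which matters for compatibility estimates
against reconstructed populations (their triple-homozygote rate is the
independence floor).  Sampling from a joint haplotype pool is available via
the synthetic module when a haplotype table exists.

One-hot encoding is presence/absence (1 iff ≥ 1 copy): homozygosity is
deliberately not retained, a dosage mode (0/1/2) exists for sensitivity
checks.  PCA mean-centres but does not variance-scale (columns are already
comparable 0/1 indicators); components come from full SVD for determinism.
Centroids are per-population means in PC space and distances are Euclidean;
they are reported raw, with an optional normalisation to a chosen pair
= 1.00 for relative-unit displays.  Default simulated-cohort size equals the
reference cohort (3,496) when comparing against it.

## Compatibility model

The matching rule had to be chosen, because "compatible" is underdetermined:
the implemented rule is **host-versus-graft** — at every retained gene the
donor's allele set (at resolution `k`) must be a subset of the recipient's,
so the graft presents no allele foreign to the recipient's CD8 T cells.
This is the only direction under which homozygous donors are systematically
advantaged and under which knocking out a gene relaxes matching — the two
phenomena the compatibility analyses are built on.  The reverse
(graft-versus-host) direction exists as an explicit option but is unused by
defaults.  Heterozygous donors require both alleles present in the
recipient, the natural extension of the subset rule.

Consequences asserted as properties: matching is reflexive but not
symmetric; shrinking the retained set is monotone (coverage can only grow);
an empty retained set is a universal donor.

Coverage is the fraction of recipients matched by ≥ 1 donor.  The seeded
random donor ordering affects only the displayed accumulation curve, never
the endpoint.  Self-pairs count by default (donor panels are drawn from the
recipient cohort, and a donor trivially covers itself); `exclude_self=True`
drops identical-id pairs.  Internally matching is indexed: recipients are
grouped by the nonempty subsets of their per-gene allele sets, so each
donor's matched set per gene is one dictionary lookup — coverage over a
3,496² cohort runs in well under a second.

Random-subset baselines draw donor panels without replacement and reuse the
precomputed all-against-all match matrix, so hundreds of replicates are
cheap.  `expected_triple_homozygotes` simulates independent-loci HWE cohorts
(vectorised across replicates) and reports mean ± sd over replicates next to
the closed form `n · Π_g Σ_i p_{g,i}²`; the default is 1,000 replicates.

## Guide design

Conventions, chosen once and stated in outputs:

- SpCas9 only, strict NGG PAM (the Rule Set 1 training convention); NAG not
  counted.
- Scoring context = 4 nt upstream + 20 nt protospacer + 3 nt PAM + 3 nt
  downstream (30 nt).  PAM hits whose context would run off the sequence end
  are excluded from scoring and reported in a separate counter.
- Coordinates are 0-based half-open internally, 1-based in human-facing
  tables.  The blunt cut falls between protospacer positions 17 and 18
  (3 bp 5′ of the PAM); minus-strand sites are mapped to plus-strand cut
  coordinates through the reverse complement, so strand symmetry holds
  exactly.
- Region membership is decided by the **cut position**, not protospacer
  overlap: the indel lands at the cut, and the frameshift position governs
  knockout.  Pipelines using overlap will count slightly more boundary sites;
  this is a known divergence risk and the reason the convention is documented
  here.
- Ectodomain = exonic cut strictly upstream of the first nucleotide of the
  first transmembrane-helix codon.  TM spans are *inputs* (per allele or per
  gene), on CDS-translation numbering or mature-protein numbering with an
  explicit signal-peptide length — no TM prediction is performed.
- High activity = ectodomain ∧ score > 0.5.  Score quartiles are descriptive
  only; the 0.5 threshold is the filter.
- Dedup across alleles keys on (protospacer, PAM); region flags OR-merge
  across occurrences (a site counts for a stage if it qualifies on any
  allele), giving the nested cascade gene body ≥ exon ≥ ectodomain ≥ high
  activity.
- HLA-C sparing removes candidates whose protospacer+PAM occurs verbatim on
  either strand of any supplied HLA-C sequence.  This is panel-restricted
  sparing, not genome-wide off-target analysis.

Rule Set 1 is the published logistic over position-specific single/
di-nucleotide indicators plus a protospacer GC-count deviation penalty
(separate per-unit weights below/above 10 GC).  The coefficient table ships
as a CSV asset whose sha256 is pinned in code; the scorer refuses to run on
a mismatched file, since silently altered coefficients would shift every
score.  Tests compare the scorer against an independent feature-by-feature
re-evaluation of the same CSV (agreement to 1e-9), which checks the scoring
path, not the provenance of the coefficients.

## Synthetic data

The registry model is a haplotype pool (distinct A-B-C triples, simplex
weights) plus one autozygosity parameter `F`: with probability `F` an
individual gets two copies of a single haplotype, otherwise two i.i.d.
draws.  Modeling homozygote excess at the whole-haplotype level was chosen
because a single parameter then produces exactly the observed signature of
interest — triple homozygotes exceeding the independent-locus expectation —
while per-gene inbreeding would require three parameters and still miss the
joint excess.  Closed forms used in tests: triple-homozygote probability
`F + (1−F)·Σw²`, hence `F̂ = (h_obs − h₀)/(1 − h₀)`.

The demo pool is the 15 reference triple-homozygous haplotypes plus 25
invented haplotypes with Zipf-like (1/rank) weights — an illustrative
structure, not an estimate of any real population.  Its heavy head makes
homozygotes common, which keeps desk-scale coverage analyses well-exercised;
real registries are far more even, so absolute synthetic coverage numbers
are not comparable to published population figures.

Toy genes default to class I scale: 8 exons, ~1.1 kb CDS starting after a
40-nt 5′UTR, TM helix encoded in exon 5, allele variants differing at a few
random exonic positions.  What passing tests show: the cascade's set
algebra, coordinate mapping across exon junctions, and scoring are correct.
What they do not show: agreement with counts derived from any specific
IPD-IMGT/HLA release, which depend on that release's allele set.

All generators are deterministic given a seed, to the byte, in emitted
files.

## Problem sizes

Default test and reproduction runs use desk-scale sizes chosen to keep
statistical checks well-powered: 500 replicate registries of n = 500 for
χ² calibration, n = 5,000 for F recovery, n = 50,000 draws for frequency
convergence, 100 random 1-kb sequences for the extraction oracle, and a
study-scale n = 3,496 synthetic registry for the end-to-end compatibility
run.  The full-registry replication checks (published coverage percentages)
require the survey's own 3,496-genotype table, which cannot be bundled; the
test that covers them states the expected file location and fails until it
is supplied.

## Known limitations

- No G/P-group collapsing, NMDP ambiguity codes, or class II loci.
- No exact HWE tests (Guo–Thompson) or LD coefficients.
- Compatibility ignores anti-HLA antibodies, KIR/NK ligand status and
  registry search mechanics; it is a genotype-containment model.
- Guide design has no genome-wide off-target scan and implements Rule Set 1
  only (no deep-learning scorers).
- Monte Carlo populations reconstructed from frequency tables have no
  between-gene linkage by construction.
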