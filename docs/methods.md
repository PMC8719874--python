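# Methods

`trioburden` implements the statistical machinery of a trio-exome "genetic
autopsy": given genotype data for case and control parent–child trios, it
calls de novo and transmitted parental-mosaic variants, compares observed
de novo burdens against a sequence-context mutation-rate null and against
control carriers, tests inherited deleterious variants for overtransmission,
and asks whether the mutated genes cluster on a protein-interaction network.
Because such study cohorts are rarely redistributable, the package ships a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes, so every stage is testable end to end.

## The mutation-rate null

The probability that a given coding single-nucleotide de novo mutation
arises in one generation depends strongly on its trinucleotide context
(transitions exceed transversions, CpG deamination dominates). The null
model assigns each of the 64 trimers × 3 alternate central bases a
per-chromosome, per-generation probability. For a gene with coding sequence
of length L, every one of the 3L possible substitutions is classified
against the standard genetic code (frame taken from the CDS start):
unchanged amino acid → synonymous; new stop codon → loss of function (LoF);
anything else, including stop-loss → missense. "Nonsynonymous" is the union
of missense, in-frame indel and LoF. The expected count of class-c de novo
mutations in gene g for n trios is

    E[c, g] = 2 n · Σ_{s ∈ g, class(s)=c} r(trimer(s), alt(s)),

linear in n and additive over genes. Flanking bases at CDS edges are
unknown; they are imputed as 'N', meaning the mean rate over the four
compatible trimers — deterministic and exactly additive under a
flank-independent table.

The bundled rate table is synthetic but realistically shaped (transitions
~4× transversions, CpG-context C>T and its reverse-strand G>A a further
~12×, lognormal jitter σ=0.35 across contexts, magnitudes ~1e-8). Absolute
scale is set by calibration: `calibrate_rate_table` rescales the table so
the whole-catalogue expected coding de novo SNV count is a chosen per-trio
mean (default 1.0). With the default toy genome this puts the exome-wide
nonsynonymous expectation at 124 trios near 85, i.e. roughly 69% of coding
substitutions are protein-altering, as expected for random coding sequence.
Indel de novo mutations are outside the trimer framework: they are modelled
as a single genome-wide per-trio rate (default 0.1) apportioned across
genes by coding length.

## Trio calling

A de novo call requires: child heterozygous with allele balance
(alt/(ref+alt)) ≥ 0.30 and depth ≥ 10; both parents genotyped homozygous
reference with depth ≥ 10 and alternate evidence ≤ max(1 read, 2% of
depth); and absence from a control carrier index (default: zero carriers
allowed). Sites with a missing genotype in any member are skipped with a
logged reason. Trios contributing ≥ 6 de novo calls are excluded outright
— an excess of Mendelian-violation calls marks sample swaps or
contamination, not biology.

A transmitted parental-mosaic call is a heterozygous child passing the same
child-side filters at a site where exactly one parent is genotyped
hom-ref yet shows an alternate allele fraction in the mosaic band
(0.03–0.20) with at least 3 supporting reads, while the other parent is
clean. The ≥3-read floor makes the mosaic band provably disjoint from the
de novo parent-tolerance rule at any depth, so a site can never be called
both ways. Sites where both parents show band-level evidence are skipped
(logged): that pattern indicates a shared artifact. Mosaic calls are
combined with de novo calls for reporting (mosaic share as a percent of
the combined callset) but enter case/control comparisons only when cases
and controls were called identically.

Genotype quality (GQ) is not modelled; allele depths and total depth carry
all the evidence in the synthetic data model.

## Burden statistics

Rate-based tests compare an observed count against its model expectation
with an exact one-sided Poisson tail, P(X ≥ obs | λ = expected), reporting
the enrichment ratio obs/expected and obs − expected. The lower confidence
bound on obs − expected shifts the exact (Garwood, χ²-based) lower limit of
the observed Poisson count — at tail probability 2.5% for a 95% two-sided
construction — down by the expectation, which is treated as a known model
constant.

Case/control comparisons are subject-level carrier tests: a trio counts
once if its child carries at least one qualifying call (effect class ∩
gene set), however many it has. The 2×2 carrier table is tested with the
two-sided Fisher exact test (minimum-likelihood rule) and the odds ratio is
reported as the conditional maximum-likelihood estimate under the
noncentral hypergeometric model with an exact-test-inversion confidence
interval — the estimate that belongs with an exact conditional test, and
slightly smaller than the sample cross-product ratio (e.g. 11.9 vs 12.0 on
a sparse table). Degenerate margins leave the odds ratio undefined and are
flagged rather than guessed.

Screen-style subsets (an actionable-gene list, ClinVar-labelled pathogenic
missense, LoF in LOEUF < 0.35 genes, optionally intersected with a prior
de novo hit list) are deterministic filters over the annotated callset;
LOEUF uses strict inequality at the threshold. No multiple-testing
adjustment is applied anywhere; reports carry nominal p-values and the
test count. Diagnostic yield is 100 × (trios with a classified genotype) /
(trios analysed), rounded to one decimal, with each trio counted once even
when it has several findings.

## Transmission tests

Inherited deleterious heterozygotes qualify under exactly one of two rules:
LoF in a LoF-intolerant gene (LOEUF < 0.35), or missense with a ClinVar
pathogenic/likely-pathogenic label. Each (variant, carrier parent) pair is
an independent Bernoulli(0.5) trial under the null of no phenotypic role;
both-parent carriers contribute two trials, X-chromosome and de novo sites
are excluded (the 0.5 null assumes autosomal biparental inheritance), and
children with missing genotypes drop out of the denominator. The test is
the exact one-sided binomial upper tail. Within-family dependence between
multiple qualifying variants is ignored, matching the trial-counting
convention; this is a documented caveat, conservative only under positive
dependence.

The recessive companion test counts "opportunities" — trios where both
parents carry qualifying heterozygotes in one gene in a trans-capable
configuration (distinct sites, or the same site allowing homozygous
formation) — and tests the number of formed biallelic genotypes against
Binomial(n, 0.25). A child heterozygous at a single site shared by both
parents is not counted as formed: one allele cannot make a biallelic
genotype and phase is indeterminable.

## Network enrichment

Mutated genes carry the maximum deleteriousness score over their mutations
(recurrently hit genes keep a multiplicity tag but count once as nodes).
Scores use the standard rank scaling −10·log10(rank fraction), so 20 marks
the top 1%. The hit set is partitioned at a configurable cutoff (default
15, strictly greater-than) and each partition is tested for an excess of
interaction edges among its members. The null resamples node sets of equal
size: uniformly, or — the default — within degree-quintile bins, which
approximates the tendency of well-connected proteins to accumulate edges
for reasons unrelated to the phenotype. The p-value is
(1 + #{null ≥ observed}) / (B + 1) with B permutations (default 9,999,
resolution 1e-4), never zero and reproducible under a fixed seed. Clusters
are connected components of the hit-induced subgraph with ≥ 3 members,
ordered by size then lexicographically; a mean-coding-length check per
cluster (in kb) guards against long genes explaining cluster membership.

## The synthetic cohort generator

The generator's defaults are the study conditions: 124 case and 573
control trios; Poisson per-trio coding de novo counts with means 1.0 (SNV)
and 0.1 (indel); 3.8% of de novo-like events parental-mosaic in origin;
qualifying deleterious parental heterozygotes at 0.113 per trio (≈14 per
124 trios) transmitted with probability `transmission_bias` (null 0.5);
~3 background inherited heterozygotes and ~0.016 biallelic opportunities
per trio. De novo SNVs are placed on (gene, position, alternate base)
proportionally to the same calibrated trimer table the null model uses, so
rate-model expectations are the true sampling means and enrichment factors
are recoverable by construction — this consistency is what the
parameter-recovery tests exercise. A nonsynonymous enrichment factor f ≥ 1
multiplies case rates for protein-altering substitutions in a designated
gene set, raising both the per-trio mean and the within-set share exactly
as a Poisson thinning argument predicts.

Read evidence: per-sample, per-site depths are gamma-Poisson with mean 89×
(dispersion 8), matching deep-exome coverage summaries; heterozygous sites
draw alternate reads Binomial(depth, 0.5); mosaic parents draw from their
true allele fraction, uniform on (0.03, 0.20) — detectable but below the
0.30 het threshold; homozygous-reference samples draw error reads at 0.5%
per read spread across the three non-reference bases (so ~0.17% supports
any specific allele). Eight noise candidate sites per trio plus a 0.1%
missing-genotype rate exercise the caller's reject paths. Deleteriousness
scores are rank-based per effect class (log-uniform rank windows chosen so
LoF and ~83% of missense exceed 15 while synonymous rarely does), and
per-gene LOEUF values are uniform on [0.03, 2.0] (≈1 gene in 6 below 0.35).

The toy genome is a fixed-seed catalogue of 200 random-sequence genes with
log-uniform coding lengths 0.3–15 kb on chromosomes 1–22. Random sequence
means internal stop codons exist (treated as ordinary codons; stop-loss →
missense) and there are no introns, so the splice-site share of LoF is
absent; the generator also omits alignment artifacts, population structure
and relatedness. Passing tests therefore validate the statistical
machinery — calling rules, expectations, test calibration, parameter
recovery — not robustness to real-data artifacts like mapping error or
batch effects.

## Numerical and design notes

- Exact tails come from scipy (`poisson.sf`, `binom.sf`, `fisher_exact`,
  `contingency.odds_ratio`); nothing resamples where an exact form exists.
- Variant identity is the "chrom-pos-ref-alt" string; multi-allelic VCF
  sites are decomposed into biallelic records, other alternate alleles
  counting as reference and per-allele depths taken from the AD vector.
- Effect-class precedence on conflicting annotations: LoF > missense >
  in-frame indel > synonymous.
- VCF records sort by numeric chromosome then position; rate-table reads
  use round-trip float parsing so write→read→write is byte-stable.
- Pipeline runs are pure functions of (config, seed): the manifest records
  SHA-256 checksums of every output, and identical inputs reproduce
  identical checksums (the manifest's own timestamp excepted).
- Problem sizes used by the test suite and acceptance script — 697-trio
  default cohorts, a 1,000-trio enrichment recovery, 10,000-replicate
  type-I checks, 9,999-permutation network nulls, and full Fisher
  enumeration to table total 40 — were chosen to make Monte-Carlo error
  small against the tolerances being asserted.

## Known limitations

- The trimer table is shaped like, but is not, an empirically fitted table;
  absolute expectations are meaningful only after calibration.
- Splice-site LoF expectation is a configurable per-intron constant
  defaulting to 0 (the toy genome has no introns).
- The caller models AD/DP evidence only; no GQ, strand bias or mapping
  quality.
- The transmission test treats multiple qualifying variants in one family
  as independent trials.
- The degree-matched network null bins degrees by quintile; very skewed
  degree distributions may warrant finer bins.
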