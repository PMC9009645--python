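# Methods

`hopfinger` implements the genotype-analysis workflow used to fingerprint
clonally maintained, mixed-ploidy germplasm collections (the motivating crop
is hop, *Humulus lupulus* L., a dioecious perennial with diploid, triploid
and tetraploid accessions) with two marker systems: a multiplexed SSR panel
scored as fragment sizes, and a small bi-allelic KASP SNP assay validated
against its GBS discovery data.

## Distances

**Bruvo distance.** For two alleles of sizes `x`, `y` (bp) at a locus with
repeat-unit length `replen`, the per-allele distance is
`d(x, y) = 1 − 2^(−|x − y| / replen)`. A locus distance between two
genotypes compares allele sets after padding the smaller set to the larger
size and minimizing the mean per-allele distance over all one-to-one
matchings, which makes the measure well defined across ploidy levels.
Padding models:

* `INFINITE` (default) — virtual alleles at distance 1 to everything;
* `ADDITION` / `LOSS` — virtual slots filled from the smaller / larger
  genotype's own alleles, each fill evaluated at its optimal matching and
  the results averaged over fills (genome addition/loss);
* `ADDITION_LOSS_MEAN` — the mean of the two.

Setting `replen = 0.001` (the package default, `ALLELE_SHARING_REPLEN`)
collapses the mutation model to band sharing: any size difference scores 1,
so the locus distance equals `1 − shared/matched`. This is the configuration
appropriate for clone identification in mixed-ploidy material, where
genome-addition assumptions over evolutionary time scales do not apply to
4x × 2x crosses happening within one generation. Pair distances are means
over loci scored in both samples (pairwise deletion); a pair sharing no
scored locus, or a sample missing everywhere, is an error rather than a
guess.

**Prevosti distance** represents each genotype at a locus as a
within-individual allele-frequency vector and takes half the L1 distance,
averaged over mutually scored loci. On bi-allelic data this equals half the
ploidy-scaled Manhattan distance between dosage vectors; it is the metric
used when comparing the SSR and SNP systems on the same samples.

**Neighbor joining** is the standard Saitou–Nei agglomeration with the
Studier–Keppler Q criterion. Ties in the Q minimization resolve to the
smallest (row, column) pair, so trees are reproducible. A negative estimated
branch length is set to zero with the deficit moved to the sibling branch,
preserving the joined path length. Because pairwise deletion already yields
complete matrices, no missing-distance ("njs") variant is needed; matrix
completeness is enforced instead. Locus bootstrap resamples loci with
replacement (default 2,000 replicates, single integer seed); the support of
an internal edge is the percentage of replicate trees containing the same
bipartition.

## Diversity statistics

* Simpson's index is the **uncorrected** `λ = 1 − Σ(n_i/N)²` over
  multilocus-genotype (MLG) counts, so a group of N all-distinct genotypes
  scores `1 − 1/N` — the convention under which the published group values
  (0.997, 0.989, 0.998) arise.
* Nei's gene diversity is the 1978 unbiased form
  `h = n/(n−1)·(1 − Σp²)` over allele copy counts.
* Evenness is E5, `(G − 1)/(e^H − 1)` with `G` the inverse Simpson and `H`
  Shannon entropy; a single-category distribution is defined as 1.
* Expected MLG richness under rarefaction is Hurlbert's
  `Σ_g [1 − C(N−N_g, n)/C(N, n)]`, evaluated with log-space binomials; the
  default rarefaction size is the smallest group's n.
* Genotypic statistics treat the unordered allele multiset as the category;
  missing calls are excluded from that locus's genotype counts.
* PIC is `1 − Σp² − Σ_{i<j} 2 p_i² p_j²`.

## Null-allele EM

Under Hardy–Weinberg equilibrium with a null allele of frequency `r`, an
apparent homozygote `A/A` is a mixture of `A/A` and `A/∅`, and a blank
(amplification-failed) diploid call is a candidate `∅/∅`. The EM iteration
apportions apparent homozygotes by the current frequencies
(`P(true hom | apparent hom) = p_A/(p_A + 2r)`), counts blanks as two null
copies (the default `include_blanks=True`; a mode excluding blanks is
provided because upstream tools differ on this), and re-estimates
frequencies from expected copy counts. Convergence is `|Δ| < 1e−8` in total
frequency movement or 10⁴ iterations. The analytic special case of a single
visible allele with blank fraction `b` has fixed point `r = √b`, used as a
test oracle. The confidence interval is a nonparametric bootstrap over
individuals (percentile, default 1,000 replicates, seeded) — a design choice,
since the reference tooling's CI construction is not documented. With a
monomorphic marker and no blanks, `r` is not identifiable away from 0 and is
reported as exactly 0 with a degenerate CI.

## Identity and marker selection

MLG assignment is exact by default: two samples share an MLG iff every
marker call, including missing status, is identical (SSR calls compared as
distinct allele sets — dosage in polyploids is generally unknown). The
`MISSING_COMPATIBLE` policy instead unions samples whose calls never
conflict, flagging transitive groups that contain mutually incompatible
members. Exact matching is the default because duplicate detection in a
repository context is followed by re-sampling, not fuzzy inference.

Minimal discriminating marker selection is minimum set cover over sample
pairs. A marker distinguishes a pair only when **both** calls are
non-missing and different — missing data never certifies a difference.
`EXACT` mode runs iterative-deepening search over subset sizes with a
coverage bound, feasible into the tens of markers; `GREEDY` is the standard
largest-gain heuristic with ties broken by panel order. The returned
certificate names, for every pair, one selected marker separating it, and is
re-verified in tests.

## Population structure

PCoA is classical scaling: double-center `−½D²`, eigendecompose, keep
positive eigenvalues. Negative eigenvalues (non-Euclidean input) are dropped
without Cailliez correction, and explained variance is normalized over the
positive part only. PAM is deterministic BUILD + best-improvement SWAP on
Euclidean distances over the principal coordinates; clustering on
coordinates rather than on the raw dissimilarity matrix improves recovery
of the true group number for large genetic data sets. The number of
coordinates passed to PAM covers ≥ 90% of positive-eigenvalue variance by
default (the choice is configurable; no published convention exists). `k`
is recommended by maximum mean silhouette; the within-cluster sum of squares
curve is returned for visual elbow inspection but never auto-selected. The
30-index majority-rule selection and admixture (sNMF-style) ancestry
estimation used in some workflows are intentionally out of scope.

## Parentage

The core check is Mendelian allele sharing: a candidate parent is excluded
if, at any locus scored in both individuals, it shares no allele with the
offspring. This holds at any parental ploidy in {2, 4} under random
chromosome segregation, so the same rule covers 2x × 2x and 4x × 2x (→ 3x)
families. The mismatch tolerance defaults to 0 and can be raised to absorb
scoring error or mutation. Null alleles create false exclusions (a shared
allele hidden on one side); the nulls-aware mode drops mismatches at loci
whose EM-estimated null frequency exceeds a threshold (default 0.05).
Likelihood-based parentage and sibship reconstruction are not implemented;
the dominant pseudo-locus export (1 = allele present, 2 = absent,
0 = missing; one pseudo-locus per catalog allele) lets users run external
likelihood software on polyploid data recoded for diploid dominant markers.
Joint mother+father trio checks are limited to diploid offspring.

## SNP panel construction and validation

Discovery filters run in the order a discovery pipeline applies them:
per-call depth masking (< 2x → missing, only when depths are supplied),
site genotype presence ≥ 90%, sample call rate ≥ 75%, then MAF ≥ 0.20 with
site missingness ≤ 10%, and optionally a no-missing-data pass. Marker
screening averages four indices — the chi-square goodness-of-fit p-value
against HWE genotype expectations (1 df, no continuity correction; the
"probability of HWE" index of genetics suites is not publicly specified, so
the chi-square p-value stands in), PIC, observed heterozygosity, and MAF —
and keeps markers with mean ≥ 0.50. The mean-of-four reading is forced:
a per-index ≥ 0.50 requirement would be unsatisfiable for MAF except at
exactly 0.5.

Assay QC removes markers that are monomorphic, lack one of the three
genotype clusters, or exceed 20% missing data, and flags samples missing
more than 20% of retained assays. Discovery-vs-assay concordance skips
cells missing on either side and classifies each disagreement uniquely:
(1) discovery het → assay hom, (2) opposite homozygotes — the signature of
a sample swap, (3) discovery hom → assay het. Mismatch-class shares are
computed over **all** mismatches before excluding high-incongruity samples
(> 20% mismatched calls), then agreement is reported both before and after
exclusion. Shares are rounded to 2 dp with largest-remainder correction so
they always total 100.00%.

The sex scan reports alleles at a sex-linked SSR carried by at least one
individual of one sex and zero of the other, with carrier counts and gene
pool classification — the basis for molecular sexing in a dioecious crop.

## Synthetic data

The generator is a stated world, not a tuning knob. Defaults reproduce the
accounting of the motivating collection: 331 cultivated + 94 wild founders
(425 unique fingerprints) expanded by 89 clone groups (63 triples, 26
quadruples, every tenth group mislabeled) to 629 accessions; 9 SSRs
including the sex-linked marker; 25 SNPs; null-allele frequencies
(0.26, 0.12, 0.08, 0.02) on four SSRs; 115/628 males. Where the stated
world is silent the defaults are fixed once at field-realistic values:
pool divergence 0.4, cultivated ploidy mix 85/10/5% (2x/3x/4x; wild
founders diploid), 3-bp repeat motifs, 6–20 alleles per SSR, SNP platform
error rates of 2% heterozygote dropout and 2% false heterozygotes with 19%
of samples swapped (emulating 12 high-incongruity samples among 63
validated).

Null alleles are modeled as a distinguished ladder allele present in the
gene pool but masked from the emitted table (a double-null diploid becomes
a missing call), so the EM's estimand is known exactly. The male-specific
allele is transmitted outside the autosomal frequency pool, so its
sex-specificity is exact. Crosses draw gametes by random chromosome
segregation (1 allele from a 2x parent, 2 without replacement from a 4x
parent) with no mutation. Platform errors are logged per cell with the
mismatch class they realize, which is what lets tests demand *exact*
recovery of injected counts.

What the generator does **not** emulate: genotyping stutter and binning
error, linkage between markers, inbreeding and family structure within
pools, allele-size homoplasy across pools, and missing data outside the
null-allele mechanism. A green test therefore certifies algorithmic
correctness against the stated world, not robustness to every artifact of
real capillary or sequencing data.

## Numerical choices

* Allele-set matching enumerates permutations (allele sets are capped at 4),
  with per-locus memoization of distinct call pairs for matrix assembly.
* Rarefaction binomials and the EM run in log/ratio space; no factorials
  overflow.
* PCoA eigenvalues below `1e−10 ×` the spectral radius count as zero.
* PAM tie-breaks are lowest-index; NJ tie-breaks smallest (row, column);
  synonym groups are named by their lexicographically smallest member.
* Bootstrap and simulation randomness flows from single integer seeds via
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Known limitations

* The exact-cover search is exponential in the worst case; panels beyond
  ~20–30 markers should use `GREEDY` (the certificate is still verified).
* The HWE index is a stand-in for an unspecified proprietary definition;
  rankings may differ near the 0.50 screen boundary.
* Bootstrap support on very small collections is dominated by the 9-locus
  resampling granularity.
* Published headline counts that depend on the study's own (undeposited)
  genotype tables — e.g. its 89 synonym sets or its exact platform-mismatch
  shares — cannot be recomputed; the acceptance suite covers the closed-form
  quantities its summary tables pin down and validates everything else
  against synthetic ground truth.
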