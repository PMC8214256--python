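# Methods

## The design being modelled

A biparental F2 population is derived from a cold-tolerant and a
cold-sensitive inbred parent; each F2 plant is selfed and its F2:3
family phenotyped for seedling survival rate (SR, %) under cold stress,
so the trait value attached to an F2 genotype is a family mean.  The k
highest- and k lowest-SR lines form two DNA bulks that are sequenced as
pools; trait-linked loci reveal themselves as allele-frequency
divergence between the pools.  A second, independent pass genotypes all
lines at individual markers inside the bulk-seq interval and maps the
trait by linkage.

## Bulk statistics and their null

All four statistics act on the 2×2 read-count table (bulk × allele) at
one biallelic SNP, oriented so that the first allele is the tolerant
parent's.  The orientation makes positive Δ(SNP-index) peaks mean
tolerant-allele enrichment in the tolerant bulk; reference-allele
orientation would be ambiguous here because both parents can differ
from the reference genome at a site.

* Δ(SNP-index) is judged two-sided; ED, G and −log10 Fisher p
  one-sided upper.
* G uses natural logs with 0·ln 0 ≡ 0 and returns 0 on a zero margin
  (no information).
* The two-sided Fisher p sums, over all tables with the observed
  margins, the probabilities not exceeding the observed table's.  The
  implementation compares exact integer table weights
  C(r₁,a)·C(r₂,c₁−a), so tie handling is exact and the result is
  correct to the final floating division.
* ED defaults to exponent 1 for statistics and region calling; the
  squared value is conventionally used only for plotting.  The exponent
  is a parameter because published peak values are not always
  attributable to a single convention.

Significance thresholds are empirical quantiles under the no-QTL null:
each bulk's tolerant-allele count is Binomial(2k, ½) (equivalent to
drawing k F2 genotypes at 1:2:1), site depth is Poisson(d̄), and reads
are Binomial(depth, p).  Quantiles are tabulated per depth class
(nearest multiple of 10 in 10–200); a window is compared against the
band at its mean site depth.  At infinite depth the null SD of Δ is
√(2/(8k)) — 0.0913 for k = 30, giving a 99% two-sided bound of ≈ 0.235;
the Monte-Carlo band reproduces this within a few percent, which is
also why a Δ > 0.48 marker-selection cut sits comfortably above the
null.

## Windows, regions, intersection

Windows are 1-based closed intervals starting at 1 + j·step; the
2000-kb/20-kb defaults are taken literally, so each site contributes to
100 overlapping windows.  Windows with fewer than 10 variants merge
cascading into the next window, coordinates expanding to the union and
the mean recomputed over the union of member sites (not a mean of
means); a trailing sparse window merges backward.  Maximal runs of
consecutive supra-threshold windows form regions (no gap bridging by
default; `max_gap` exposes it), with the peak reported as the extremal
window mean.  The QTL call is the interval intersection of one region
per method, all mutually overlapping; interval lengths are reported as
end − start (matching how such lengths are conventionally printed),
with kb to 1 decimal and Mb to 2.

## Linkage stage

Markers are non-synonymous SNPs with Δ above the threshold inside the
bulk-seq interval, thinned to n by greedy max–min physical spacing.
Adjacent-marker recombination fractions are maximum-likelihood
estimates for F2 codominant markers (9-class multinomial likelihood,
bounded scalar optimisation) and map to cM by Kosambi's function,
25·ln((1+2r)/(1−2r)) — the rice convention.  The scan is Haley–Knott
regression: at each 0.5-cM grid point the QTL genotype distribution
given the flanking markers comes from the F2 three-state Markov chain
(no interference), and SR is regressed on expected additive dosage and
heterozygosity.  Missing genotypes drop a line at that position only.
A full ICIM-style cofactor search is deliberately not implemented: for
a single-interval scan the single-QTL model is sufficient, and the
permutation threshold (empirical critical value of the per-permutation
maximum LOD, order statistic at 0-based index ⌈n(1−α)⌉) controls the
scan-wide error.  The report prints both the signed additive effect
(positive ⇔ tolerant allele raises SR) and the contributing-parent
label, because a sign alone is ambiguous across coding conventions.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes: Mendelian 1:2:1 segregation with Haldane (Poisson, uniform)
crossovers; an SR phenotype SR = μ + a·(g−1) + d·1[g=1] + ε with ε
scaled so the QTL explains the target PVE at the line level in
expectation (replicate measurements carry √m-inflated noise so their
mean recovers the line-level SD); truncation to [0, 100] applied after
noise, with PVE defined pre-truncation; extreme-tail bulk selection
with deterministic id-ordered tie-breaking; Poisson–binomial pooled
read sampling; and a seeded reference genome whose gene models tile
both strands, with one CDS guaranteed to cover the QTL so a
non-synonymous causal SNP exists (the codon there is forced to GAA,
every substitution of which can be non-synonymous regardless of frame
offset).

Defaults mirror the motivating study: 460 lines, 30+30 bulks, ~50×
pool and parent coverage, QTL PVE ≈ 0.26, three phenotyping replicates.
The default genome — two 30-Mb chromosomes at 1 SNP/kb and 4 cM/Mb —
is a scaled-down stand-in for a 12-chromosome rice genome; simulation
studies in the test suite and acceptance script use two 10-Mb
chromosomes at 0.5 SNP/kb so that twenty end-to-end replicates run in
well under a minute.  Not modelled: sequencing error, indels, F2→F3
heterozygote segregation within families (the F2 genotype's expected
value stands in for the family mean), selective-genotyping bias,
segregation distortion, and real linkage-disequilibrium structure.
Passing tests therefore demonstrate correctness of the inference
machinery under the design's idealised assumptions, not robustness to
artefacts of real sequencing data.

## Numerical choices and edge cases

* Zero-depth bulks make a site's statistics undefined; such sites are
  excluded with a count, and zero-variance phenotypes yield zero LOD
  rather than an error.
* Sample skewness/kurtosis use the moment estimators g1 and g2 and are
  reported missing for constant samples.
* Recombination fractions estimated at ≥ 0.5 are flagged unlinked and
  capped at 0.499 so map distances stay finite.
* Scan ties at equal LOD resolve to the leftmost grid position; the
  1-LOD support interval extends to the nearest positions where the
  LOD has dropped by one.
* All randomness flows from one master seed through named substreams
  (sites, crossovers, phenotype, reads, reference, null band,
  permutations), so any stage can be regenerated independently and
  reruns are byte-identical.

## Known limitations

The window-level test compares a window's mean statistic against
per-site null quantiles, which is conservative (a mean of many null
sites is much less variable than one site); this inflates interval
widths rather than false-positive rates, and matches the practice of
drawing per-site confidence bands on window-averaged profiles.  The
haplotype test (Kruskal–Wallis; Welch ANOVA would be the parametric
alternative) treats lines as independent, which extreme-bulk selection
technically violates.  Candidate classification uses the standard
nuclear code only, with stop gain/loss folded into the non-synonymous
class and flagged in a note; in fully random synthetic CDS sequence,
internal stop codons occur and appear as such labels.
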