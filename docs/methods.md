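# Methods

`sweepset` implements a polygenic-selection analysis pipeline for phased,
ancestral/derived-polarized SNP panels: two per-SNP selection scans, gene
mapping and gene-set preprocessing, two permutation gene-set enrichment
engines with FDR control, and disease-gene outlier flagging, together with
a forward Wright–Fisher simulator used to validate every stage.

## Haplotype-homozygosity scan (iHS)

For a focal SNP and a core allele, the extended haplotype homozygosity at a
flanking SNP x is

    EHH(x) = sum_h C(n_h, 2) / C(n_core, 2),

where the sum runs over the distinct haplotypes spanning focal..x among the
core-allele carriers: the probability that two random carriers are
identical over that stretch. EHH starts at 1 and can only decrease. The
curve is extended outward until the first SNP where EHH < 0.05 (that point
is included), and the integrated haplotype homozygosity iHH is the
trapezoidal integral of EHH against genetic distance (cM). If the walk
instead reaches the chromosome end, or a physical gap between consecutive
SNPs larger than 200 kb, the integral never closes and the statistic is
undefined at that SNP (the undefined reason is reported). The gap rule is
applied between consecutive SNPs, and the stopping rule is read as "extend
while EHH ≥ 0.05", which is the only reading consistent with a decaying
curve; both are switchable parameters.

The unstandardized score is iHS_raw = ln(iHH_ancestral / iHH_derived) with
each iHH summed over the left and right curves. Because iHH depends
strongly on allele frequency, raw scores are standardized to mean 0 and
variance 1 within derived-allele-frequency bins (20 equal-width bins by
default; bins with fewer than two defined scores are merged into a
neighbor). SNPs with minor-allele frequency below 0.05 are skipped.
Candidate selection downstream uses |iHS| — both extremes are sweep
signals, depending on which allele hitchhiked.

## Cross-population composite-likelihood scan

The scan contrasts a selective-sweep model against neutral drift for the
objective population's allele frequency p1 given the reference
population's p2. Under drift, p1 ~ Normal(p2, ω p2(1−p2)) truncated to
(0, 1) and renormalized; ω is a drift coefficient. Under a sweep centred
at a grid point, a lineage at recombination distance r (Morgans) escapes
the sweep with probability c = 1 − exp(−r/q), where q ≥ 0 (Morgans) scales
with sweep strength; with probability p2 the sampled allele hitchhiked
(p1 = (1−c) + cZ) and otherwise p1 = cZ, with Z the truncated-normal drift
variable. q = 0 forces c = 1 and reproduces the neutral density exactly, so
the score

    S(grid point) = 2 [ max_q L(q) − L(0) ]  ≥ 0

is a likelihood-ratio-type statistic, with L the weighted log composite
likelihood of the window.

Windowing follows the standard grid design: grid points every 200 bp, the
50 retained SNPs nearest each grid point (up to 25 per side), SNPs
polymorphic in both population samples only. SNP k is down-weighted by
w_k = 1/m_k where m_k counts window SNPs with r² ≥ 0.95 to k in the
reference haplotypes, so a block of perfectly correlated SNPs contributes
like one observation. Each SNP inherits the score of its nearest grid
point (ties resolved toward the lower coordinate) and SNP scores are
normalized genome-wide to mean 0, variance 1, separately per population
pair.

Numerical choices: the q grid is {0} ∪ 15 log-spaced points in
[1e−6, 1e−1] Morgans; ω is estimated by the method of moments
(mean of (p1−p2)²/(p2(1−p2)) over retained SNPs, floored at 1e−4) — note
this estimator is intentionally the simple moment form and is inflated by
SNPs with extreme reference frequencies; per-SNP log densities are floored
at −20. The floor matters: observed sample frequencies can fall outside
the sweep density's support (density 0), and with an unbounded penalty a
single such SNP at weight 1 would dominate an entire window and the
genome-wide noise tail. e⁻²⁰ ≈ 2·10⁻⁹ is far below any density resolvable
from sample frequencies at hundreds of chromosomes, so the floor never
binds for ordinary observations while keeping scores driven by coherent
multi-SNP patterns.

## Gene mapping and gene-set preprocessing

When two position mappings of the same SNPs are supplied (e.g. two
assembly-remapping tools), only SNPs placed at the identical chromosome
and position by both are kept. Genes are represented by the union interval
of their isoforms (utmost start to utmost end, 1-based inclusive); a SNP is
assigned to every gene whose union interval contains it. No flanking window
is added by default (configurable).

Gene-set hygiene: members are restricted to genes with at least one
assigned SNP; sets with fewer than 10 genes are discarded; near-duplicate
sets are merged greedily — while any pair has Jaccard similarity above
0.95, the highest-similarity pair is replaced by its union (similarity ties
broken lexicographically, merged names joined with "+", lineage recorded) —
and the size floor is re-applied after merging. Jaccard is the default
similarity; the overlap coefficient is available behind a flag. The
procedure is deterministic and independent of input order.

## Enrichment engines

Both engines test a set against permutation nulls and report
p = (1 + #{null ≥ observed}) / (1 + B), so p > 0 always.

**Sum engine.** Each gene's score is the maximum |normalized SNP score|
over its SNPs — the max (rather than mean or sum) keeps the statistic
sensitive to a single strong sweep inside a long gene. The set statistic is
the sum of member gene scores. Genes spanning more SNPs have stochastically
larger maxima (gene-length bias), so null sets are drawn gene-by-gene from
SNP-count-matched quantile bins (10 bins, small bins merged; ties in SNP
count never split across bins). An exhaustive-enumeration null is available
when all genes fall in one bin and the subset count is small; it is used as
an oracle in the tests. Overlap correction is a single pass: sets are
ranked by p (ties: smaller set, then name); walking down the ranking, genes
claimed by better-ranked sets are removed, sets falling below 10 genes are
dropped, and surviving pruned sets are re-tested.

**Candidate engine.** Candidate SNPs are those with |score| in the top
1 % genome-wide (5 % is the common alternative; ties at the cutoff are all
included). The set statistic is the number of member genes containing at
least one candidate SNP (a SNP-counting mode is available behind a flag).
Each permutation redraws the same number of SNPs uniformly without
replacement from all scored SNPs, which preserves the gene-length exposure
of every set. Because the counting statistic is integer-valued, the
engine's p-values are discrete and the test is conservative at small
candidate counts, never anti-conservative.

q-values are Benjamini–Hochberg adjusted p-values with enforced
monotonicity; sets are reported at q ≤ 0.09. Disease-gene flagging applies
a 1 % upper-percentile cutoff to the same gene scores the sum engine uses
(genes tied with the cutoff are all flagged; flags are invariant under
monotone transformations of the scores) and summarizes the overlap with a
user-supplied disease list by a hypergeometric tail over the scored-gene
universe.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, without claiming demographic realism.

*Frequencies.* Ancestral derived-allele frequencies are Uniform(0.05,
0.95) — an ascertainment-like prior keeping most SNPs polymorphic — and
each population's frequency is Balding–Nichols:
Beta(p(1−F)/F, (1−p)(1−F)/F) with differentiation F per population
(default 0.05 each, roughly continental-scale). Allele counts are
binomial at 2n chromosomes, and monomorphic-in-sample SNPs are flagged.

*Haplotypes.* Each population starts from 2N mosaics of K = 20 random
founder haplotypes (independent switch points at 300 per Morgan, giving
~0.3 cM ancestral blocks) and evolves as a random-mating diploid
Wright–Fisher population with per-generation Poisson crossovers on the
genetic map. Additive selection (fitness 1, 1+s, 1+2s) acts at the sweep
site in the first population. Hard sweeps run to fixation; incomplete
sweeps stop the first generation the derived frequency reaches the target.
All populations are sampled at the same generation (the others run exactly
as long as the sweep population). By default the beneficial allele starts
as a single-origin standing variant (2 % of chromosomes sharing one
haplotype background; `sweep_init_freq=0` gives a new mutation) — copies
scattered over many backgrounds would constitute a multiple-origin soft
sweep with essentially no haplotype or hitchhiking signature. A lost
allele triggers a retry with a large-stride seed increment (so nearby user
seeds stay independent), up to 100 attempts.

*Coordinates.* Chromosomes are 1 Mb segments with compressed physical
coordinates; the genetic length is chosen per use. Haplotype-scan studies
use 100 cM/Mb (a ~1 Morgan chromosome: essentially every meiosis
recombines, and EHH decays — on the coalescent scale ~1/(4N) Morgans —
well inside the chromosome). Cross-population-scan studies use
10–20 cM/Mb so that 50-SNP windows are much shorter in genetic distance
than a sweep footprint (~s/ln(2Ns) Morgans), as in dense real panels.
Physical-unit rules (200 bp grid, 200 kb gap, 25 kb sweep-proximal
windows) keep their stated values in these compressed coordinates.

*Annotations.* Genes tile the chromosome with variable lengths and 1–3
isoforms whose union spans the gene; gene sets are drawn with configurable
sizes and pairwise Jaccard overlaps; the "planted" set contains every gene
overlapping the sweep position ± a flank, padded with random genes. The
polygenic study simulates several chromosomes, each with its own sweep,
and plants all sweep-region genes in one set — the multi-locus signal the
enrichment engines are designed for. A disease list overlaps the planted
genes at a configurable rate.

*What is not emulated.* New mutation during the simulation, demographic
history beyond a single split with drift, background selection, genotyping
error and missingness, and realistic gene/SNP density heterogeneity.
Passing validation therefore shows the statistics behave as designed under
their own assumptions — calibrated nulls, power against planted signals —
not that real-data performance is guaranteed.

## Validation studies and problem sizes

The standard studies (module `sweepset.experiments`) use panel sizes
chosen to resolve the quantities being checked at desk scale: neutral
calibration and sweep power on 2000-SNP, 200-diploid panels (20 sweep
replicates at s = 0.1, incomplete to 0.95); haplotype-scan localization on
800-SNP, 100-diploid panels (incomplete sweeps to 0.6, where the statistic
is most sensitive); end-to-end power on twelve-chromosome polygenic studies
(1000 SNPs and one s = 0.3 sweep per chromosome, 30 sets of 20 genes,
2000/10000 permutations) — spreading the planted signal over many loci is
what makes it polygenic, and is what the candidate engine's gene-counting
statistic is designed for. Because a planted sweep occupies more than 1 %
of these small genomes, "genome-wide" percentile cutoffs for sweep
replicates are computed on the neutral complement (grid points more than
150 kb from the sweep); at real genome scale the genome-wide and neutral
distributions coincide. Cross-replicate calibration bands account for the
spatial clustering of exceedances (nearby SNPs share windows), which makes
the effective sample size the number of independent windows rather than
the number of SNPs.

## Known limitations

- The composite-likelihood model is evaluated on sample frequencies
  directly; no binomial sampling correction is applied (by design), so
  near-fixed differences at small samples are handled by the density floor
  rather than modeled.
- The moment estimator of ω has a heavy-tailed summand and is inflated
  when reference frequencies are extreme; its expectation can diverge for
  strong differentiation. It is floored, switchable, and can be overridden
  with an externally estimated value.
- One-pass pruning does not iterate to a fixed point; heavily nested
  collections may retain residual overlap effects.
- The candidate engine's gene-counting statistic loses power when
  candidate SNPs concentrate in very few genes (a single clustered sweep);
  it is designed for polygenic, multi-locus signals.
- EHH decay requires chromosomes several times longer (in Morgans) than
  the coalescent homozygosity scale 1/(4N); short maps leave most SNPs
  undefined, which the output flags explicitly.
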