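# Methods

## Problem and scope

`hotscan` reimplements, as a tested pipeline over synthetic data, the chain
of analyses that relates an in-vitro genome-wide binding-site catalog for a
hotspot-positioning zinc-finger protein (affinities in reads per million,
ppm) to in-vivo recombination-hotspot usage read out by H3K4me3, DSB (DMC1)
and protein-ChIP peaks. The stages are: site classification, r-scan
detection of hotspot-deficient regions, chromatin-category enrichment with
Poisson errors, affinity-quintile barrier analysis, and positional
profiles. Raw-read processing (alignment, peak calling, HMM domain
segmentation, motif discovery, FPKM estimation) is out of scope: peaks,
domains and expression values are inputs.

## Coordinates and overlap

All intervals are 0-based half-open (BED convention); 1-based dialects must
be converted at the reader boundary. "Overlap" always means at least one
shared base pair — a site belongs to a category if it crosses into or is
encapsulated within it — and abutting half-open intervals do not overlap.
Membership queries run on merged, sorted region arrays with binary search.

## Site classification

A site is an in-vivo candidate when it overlaps the reference-strain
H3K4me3 peak set or the DMC1 set (the union rule; candidacy is deliberately
not conditioned on the second strain). Among candidates, a site overlapping
both strains' H3K4me3 with no DMC1 peak is promoter-like activity shared
across binding specificities, classified `ambiguous` and excluded from all
usage statistics; remaining candidates are `in_vivo`, non-candidates
`in_vitro_only`. A candidate with DMC1 evidence is `in_vivo` even when both
strains share its H3K4me3. The partition is exhaustive and exclusive and is
asserted on every run.

## r-scan statistic

For sorted positions on one chromosome with inter-event distances
U_1..U_{n-1}, the r-scan length is

    R_i^(r) = U_i + ... + U_{i+r-1} = pos_{i+r} - pos_i ,  i = 1..n-r.

Long spans indicate dispersion (depletion); short spans clustering (exposed
as a mode flag, not a default output). Spans are pooled over chromosomes
and the k_max largest per order r (defaults r_max = 24, k_max = 10; ties
broken by chromosome then start) are tested against an empirical null:
n_null replicate position sets (default 10,000) drawn per chromosome with
the test set's per-chromosome counts, either without replacement from a
background catalog or uniformly along the chromosome. Drawing per
chromosome keeps chromosome ends and count imbalance in the null.
p = (1 + #{null m_k^(r) >= observed}) / (n_null + 1), so p is never zero;
Benjamini-Hochberg is applied jointly across the r_max x k_max family
(per-r adjustment available as a config option). Spans with adjusted
p < alpha (default 0.05) are significant.

Note a granularity interaction: with n_null = 1,000 the smallest attainable
p is 1/1001, which is larger than the leading joint-BH threshold
alpha/(r_max * k_max) ~ 2.1e-4, so a single extreme span cannot reach
significance at that replicate count; a genuine depleted region produces a
large batch of minimal p-values across orders and passes easily. This makes
small-n_null runs conservative, never anti-conservative.

### Region extent: merge then localize

Significant spans are merged (gap 0) into clusters. A cluster is then
reduced to the union of its significant spans of the smallest significant
order r*. Rationale: a single extreme low-order gap makes every high-order
window containing it extreme too; those windows add up to r-1 ordinary
inter-event distances on either side and would inflate the region by their
full extent without contributing independent evidence. The smallest
significant order localizes the depletion most tightly; in the
implanted-gap simulations this recovers a 300-kb site-free gap with ~98 %
reciprocal overlap, where the plain union of all significant spans would
pad it by ~100 kb of normally spaced sites per side. The trade-off: if a
broad low-density region contains one outright gap, the call can collapse
to that gap; for the depletion structures simulated here this was never
limiting.

Regions overlapping user-supplied assembly-gap/low-mappability annotations
are removed. Each surviving region is cross-referenced against the
in-vitro catalog: it is "truly deficient" (in usage, not in binding sites)
when its site density is at least half the genome-wide density
(threshold_fraction configurable).

## Enrichment statistics

Usage of a category = n_used / n_total over non-ambiguous sites, with a
Poisson standard error sqrt(n_used)/n_total on the numerator count
(binomial SE available as an option). For binary partitions the negative
class is defined as "does not overlap the category", so boundary-straddling
sites count once and the totals sum exactly to the non-ambiguous catalog.

Affinity quintiles are equal-count bins (sizes differ by at most one,
stable ties) cut on all non-ambiguous sites genome-wide before stratifying
by chromatin; per quintile the closed-chromatin usage is divided by the
open-chromatin usage. Closed = merged union of the H3K9me2/H3K9me3 domain
sets; open = its genomic complement. The ratio's SE uses the delta method
on the two Poisson numerators. Expression quartiles are equal-count bins by
expression with stable tie order (zero-expression genes fall in the bottom
bins).

Rank-sum comparisons use the two-sided Mann-Whitney test: exact enumeration
when n_a*n_b <= 400 with no ties, otherwise the normal approximation with
tie correction. ppm = count * 1e6 / library size. Site density is reported
to 2 decimals (sites/Mb) and recombination rate to 3 decimals
(cM/Mb = 100 * recombinant fraction / Mb), matching the precision of the
published worked examples the acceptance script reproduces.

## Positional profiles

Composite coverage profiles average a coverage track over oriented site
windows (minus-strand windows reversed), excluding sites truncated at
chromosome ends; the anchor is the interval center by default or the motif
start. Nucleotide-frequency profiles align sites on the motif start,
reverse-complement minus-strand windows, and report per-position A/C/G/T
frequencies (summing to 1) with the requested flank. The SNP-density
profile counts SNPs per offset in a 2-kb window ([-1000, +1000) around the
oriented center) and divides by the window mean, so the profile mean is
exactly 1; smoothing is off by default (optional odd-width moving average).
For a piecewise-constant SNP rate e-fold enriched over the central m bp,
the plateau ratio is e / (1 + (e-1) m/W) — the oracle used by the closure
tests. Binned log2 enrichment scales both tracks to equal totals, then
reports log2((sample + pc)/(control + pc)) per 2-kb bin with pseudocount
pc = 1, so empty bins give 0, never infinities.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions.

- Genome: 2 chromosomes x 10 Mb (minutes-scale on one CPU); 2,000 sites of
  300 bp placed uniformly outside any implanted site-free gaps, with a
  centered 31-bp motif on a random strand. 31 bp is the informative span of
  the binding site; the coverage-geometry checks additionally use the 34-bp
  experimentally determined site length.
- Affinities: ppm = exp(N(1.6, 1.0)) (median ~5 ppm), a heavy right tail
  as in sequencing-based affinity estimates.
- Domains: alternating-state renewal mosaics with exponential segment
  lengths; in-state mean lengths 200 kb (H3K9me2, cLAD), 150 kb (H3K9me3),
  30 kb (genes) at target genome fractions 0.35/0.30/0.15/0.40. Segment
  scales are shrunk relative to megabase-scale real domains so that a
  20-Mb toy genome holds enough segments for stable realized fractions.
  Genes carry expression values (30 % zeros, else exp(N(1.5, 1.5))).
- Activation: logistic in log-affinity,
  logit p = b + a*ln(ppm) - sum(penalty_d * in_domain_d) + c*in_top_gene,
  with b = -1.0, a = 1.0, penalties 1.2 (H3K9me2), 2.0 (H3K9me3),
  0.8 (cLAD), -0.4 (gene bodies: a bonus), c = 0.6 for the top expression
  quartile. The source account of the chromatin barrier is qualitative; the
  logistic is the minimal monotone model reproducing the observed
  affinity-overcomes-barrier trend, and the baseline is set so that about
  half of the catalog activates, mirroring the published 48 % usage. The
  remaining magnitudes are arbitrary and documented as such.
- Peaks: each activated site emits H3K4me3 in both strains (~900 bp) and a
  DMC1 interval, all sharing one jittered midpoint, with the DMC1 interval
  containing both H3K4me3 intervals. This containment makes the ambiguous
  class exactly the seeded promoter-like peaks (both strains, no DMC1;
  default 4 % of activated-site count, at otherwise-silent sites): with the
  fraction at zero, zero sites classify ambiguous. The top affinity decile
  of activated sites also emits a protein-ChIP peak, mirroring the sparse
  in-vivo ChIP recovery.
- SNPs: Poisson at 0.004/bp (the B6-vs-CAST subspecies scale), multiplied
  by e (default 3) within the central motif of historically active sites.
  History is collapsed to the current activation flag — sufficient to test
  the profile estimator, but it cannot represent sites active historically
  and silent today.
- Sequence (optional): uniform background with the consensus implanted at
  each motif position with weight 0.5, raised to 0.9 at the five
  near-invariant positions (1-based 8, 11, 13, 15, 16), reverse-complement
  on minus strands.
- Coverage: every retained fragment of length L (default 177) fully
  contains the m-bp motif, giving L - m + 1 admissible starts and a
  trapezoidal per-site pileup of span exactly 2L - m (320 bp for L = 177,
  m = 34). Stratified offset allocation makes the coverage integral exactly
  depth x L per site.

Everything is deterministic given the seed (independent spawned streams per
component), and identical configs produce byte-identical files.

What the generator does not emulate: mappability artifacts and repeats,
read-level noise, sequence-composition bias, correlated domain placement,
genuine evolutionary hotspot turnover, and crossover interference. Passing
closure tests therefore demonstrates estimator correctness under the
model's assumptions, not robustness to those real-data complications.

## Problem sizes used in tests and acceptance runs

Enumeration toy: 3-of-6 background positions, 2,000 replicates (total
variation < 0.05 vs the exact C(6,3) distribution). Type-I: 20 null
simulations of 2,000 uniform sites on 10 Mb with n_null = 1,000. Power: one
implanted 300-kb gap at ~5-kb mean spacing, n_null = 1,000. Quintile
monotonicity: 10 seeds at 8,000 sites, ratios averaged across seeds before
the monotonicity check (single-seed ratios carry ~0.05 binomial noise
against adjacent-quintile gaps of similar size). SNP closure: rate 0.01/bp
so the plateau mean is estimated to a few percent. These sizes were chosen
once as the smallest giving clearly interpretable checks.

## Known limitations

- The empirical null treats events as exchangeable draws; spatially
  structured usage (the chromatin barrier itself) violates this for the
  in-vivo set tested against the in-vitro background, which is exactly the
  signal the analysis exploits — but it means "significant" spans should be
  read as depletion relative to the catalog, not relative to a mechanistic
  model of activation.
- With heavy multiplicity and small n_null, joint BH is conservative (see
  the granularity note); use n_null >= 10,000 for final analyses.
- Region localization by smallest significant order can under-cover broad
  shallow depletions containing one dominant gap.
- The Poisson SE on a usage fraction ignores denominator variance; the
  binomial option is preferable when fractions approach 1.
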