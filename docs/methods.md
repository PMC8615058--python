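# Methods

## Data model and filtering

A cohort is a matrix of (methylated, total) read counts over CpG sites ×
samples. Sites are keyed by the plus-strand cytosine position, 0-based; a
minus-strand record at `pos + 1` is summed into the plus-strand site, since
all downstream statistics are per CpG, not per strand. Missing (site, sample)
pairs carry `total = 0`, never NaN, so every filter is a statement about
coverage.

Three branches refilter independently from the assembled matrix, mirroring
how the per-site, region and per-sample analyses make different coverage
demands:

| branch | coverage rule | saturation rule |
|---|---|---|
| DMC | ≥ 10 reads in **every** sample | pooled methylation ≤ 0.999 |
| DMR | ≥ 1 read in every sample | pooled methylation ≤ 0.999 |
| UMR | ≥ 10 reads **in that sample** | — |

The saturation ceiling guards against bisulfite non-conversion artifacts. Its
scope is configurable. The default (`site_mean`) compares the pooled
site-level methylation (Σ meth / Σ total across samples) against the ceiling.
The alternative (`any_sample`) drops a site whenever a single sample exceeds
it; we do not recommend it at moderate coverage, because a per-sample ratio
of exactly 1.0 is a routine binomial outcome wherever true methylation is
high (at 15X and a true level of 0.90, each sample sits at 1.0 with
probability 0.9¹⁵ ≈ 0.21, so across 20 samples nearly every legitimately
high-methylation site is destroyed — precisely the sites where
hypomethylation in cases must be detected).

Complete-case filtering at 10X is deliberately harsh: with ~15X mean
coverage, the probability that all 20 samples reach 10X at one site is
roughly 0.9²⁰ ≈ 0.1, and the pipeline's own simulations retain ~2,500 of
~19,500 sites. This attrition is a property of the study design, not of the
implementation; recovery metrics therefore separate caller sensitivity
(recall over sites the filters retain) from filter attrition (`recall_all`).

## Batch correction

Samples carry a categorical batch ("origin") label. Per site, ratios are
clipped to [0.005, 0.995], logit-transformed, and regressed (OLS, all sites
solved in one least-squares call) on an intercept, group indicators and
batch indicators. The fitted batch component, re-centred to zero mean across
samples, is subtracted, and the result is mapped back through the inverse
logit. Keeping the group term in the design is what prevents the correction
from absorbing genuine case–control differences; re-centring preserves each
site's cross-sample mean exactly in logit space. A batch that coincides with
a group is refused: the two effects are then algebraically inseparable, and
silently proceeding would subtract biology.

## DMC calling

Classical pooled-variance Student's *t* per site on (optionally
batch-corrected) ratios, two-sided; Welch's form is a flag. Degenerate
inputs: zero pooled variance with equal means gives t = 0, p = 1; with
unequal means the p-value is clamped to 1e-300 and t = ±∞. BH adjustment
runs over all tested sites by default, with the |Δ| ≥ 0.08 effect floor
applied afterwards; `filter_then_fdr` restricts the BH universe to sites
passing the floor first (the two orders are both defensible readings of the
criteria and give the analyst the choice).

A known behaviour of *t*-tests on binomial ratios near the boundary: when all
samples of one group land on exactly 0.0 or 1.0, the within-group variance
collapses and |t| inflates. On simulated null cohorts this produces a small
number of spurious but formally significant sites in roughly one null genome
in eight; the average false-discovery proportion stays within the nominal
level plus Monte-Carlo error (asserted in the acceptance suite), but
analysts should expect occasional boundary artifacts rather than a literally
empty significant set under the null.

## DMR calling

On the 1X branch, each site's p-value is combined with all neighbours within
±200 bp on the same chromosome by the unweighted Stouffer rule
(z\* = Σ Φ⁻¹(1−pⱼ)/√k; an isolated site is returned unchanged, and the k = 1
case is the exact identity rather than a float round-trip through Φ). The
combined p-values are then BH-adjusted across all sites — without
multiplicity control a genome-scale scan emits chance runs at a high rate
(~3.5 false regions per 5,000-site null genome in our measurements; ~0 with
it). Maximal runs of significant sites with one delta sign and inter-site
gaps ≤ 200 bp become regions; a region is reported iff ≥ 2 member sites pass
the 8% effect floor, the mean delta passes it too, and the minimum member
corrected p is below 0.05. Sign homogeneity is required because a region
mixing hypo- and hypermethylation has no single methylation difference.
Region span runs from the first to the last member CpG, half-open.

Every emitted region retains its member-site row indices so the three
conditions can be re-audited from the output — the test suite does exactly
that on randomized inputs.

## UMR segmentation and case-exclusive consensus

Per sample, after the 10X per-sample filter:

1. **PMD masking.** CpGs whose 101-CpG centred rolling **median** methylation
   falls in [0.10, 0.60], in maximal runs of ≥ 100 CpGs, are masked as
   partially methylated domains. The median, not the mean, is the operative
   choice: a PMD is a domain whose individual CpGs sit at intermediate
   methylation, whereas a fully unmethylated region (CpG island or genuine
   UMR) embedded in high background makes the window *bimodal* — its mean
   drifts into the PMD band while its median does not. With the mean, a
   20-CpG unmethylated block plus a nearby island reliably fabricates a
   multi-kilobase false PMD that swallows the very UMRs the step is meant to
   protect.
2. **Candidate runs.** Maximal runs of ≥ 4 consecutive retained CpGs, each
   below 0.30, with run average < 0.10.
3. **Empirical FDR.** Candidate score = CpG count. The per-site ratios are
   permuted genome-wide 20 times; candidates are kept above the smallest
   score whose estimated FDR (mean null count at or above the score divided
   by the observed count) is ≤ 5%. Twenty permutations keep the run
   desk-scale while the score distribution (small integers) is stable.

Consensus: the genome is partitioned into atomic intervals at every region
boundary across all samples; an atom is kept when strictly more than 75% of
case samples have a UMR covering it (for 14 cases: at least 11) and no
control sample does; adjacent atoms merge. A 1-bp overlap counts as
coverage. One consequence of the strict per-CpG run rule worth knowing: a
single read-sampling blip (an observed ratio ≥ 0.30 at a truly unmethylated
CpG, probability of order 10⁻³ per site per sample at 10–15X) splits that
sample's run in two. If two case samples blip at overlapping positions
inside the same region, the atom between the halves falls below the 75%
bar and the consensus splits into two pieces; across simulated cohorts this
happens in roughly one run in ten. An HMM-based segmenter would smooth over
such blips at the cost of a far less transparent model.

## Annotation

Functional classes resolve by precedence promoter > 5′UTR > 3′UTR > exonic >
intronic > intergenic; a site touching several genes takes the
highest-precedence class while every gene hit is retained. The promoter is
the 1,000 bp strictly upstream of the strand-aware TSS ([TSS−1000, TSS) on
plus, [tx_end, tx_end+1000) on minus). CpG context uses the conventional
2 kb shores and 2–4 kb shelves, half-open so a site exactly 2 kb past an
island edge is already shelf. Both classifications partition the site set by
construction.

## Bias-corrected enrichment

Genes with more CpGs have more chances to contain a DMC; genes whose DMCs
have larger |Δ| are easier to detect. Both are absorbed into a per-gene bias

    bias = nCpGs + nDMC / Σ|ΔDM|  (= nCpGs + 1 / mean|ΔDM|; nCpGs if nDMC = 0)

computed over the gene's significant DMCs (an all-CpG variant of ΔDM would
be a one-line change; the significant-DMC reading matches the definition of
the second term as an effect-size penalty). The probability-weighting
function is an isotonic (PAVA) regression of the 0/1 DMC indicator on the
bias rank, floored at 1e-6 — monotone and parameter-free where a spline
would need knot choices. Category significance uses the Wallenius noncentral
hypergeometric distribution (scipy's implementation) with odds = mean weight
inside the category / mean weight outside; with equal weights this is the
exact hypergeometric, which scipy reproduces to ~1e-13, so no special case
is needed. Both tails are reported (under-representation is as informative
as over-representation here) and BH runs across categories, separately for
all / hypomethylated / hypermethylated DMC gene lists. The mean-weight odds
reduction is exact when weights take one value inside and one outside the
category and is an approximation for fully heterogeneous weights — the test
suite's sampling oracle therefore uses the two-weight design.

## Clinical statistics

Pearson chi-square without continuity correction, all-zero columns dropped
before testing (df = (r−1)(c′−1)); two-sample *t* (pooled or Welch)
reconstructed from printed group summaries (mean, SD, n). These reproduce
the cohort-description statistics a reader can check directly from printed
counts.

## Synthetic cohort generator

The generator emulates the statistical regime the analysis assumes, not real
genomes:

- **Design**: 6 controls, 7 MDH + 7 MDL cases; two origins as batches,
  balanced within groups, with logit offsets (0, 0.3).
- **Genome**: 2 × 1 Mb chromosomes, ~20,000 CpGs (~1 per 100 bp), 60 CpG
  islands holding ~9% of sites, 40 genes with exon/UTR structure.
- **Baseline methylation**: islands ~ Beta(1,19) (mean 0.05), background ~
  Beta(18,2) (mean 0.90) — the canonical bimodal methylome.
- **Coverage**: negative binomial, mean 15, dispersion 0.3 in the
  relative-excess parameterization (variance = μ(1+φ)); mildly
  overdispersed Poisson, as sequencing depth is.
- **Counts**: meth ~ Binomial(total, true ratio); true ratio = clip(baseline
  + planted effect + N(0, 0.03)) shifted by the batch offset on the logit
  scale. Effects are planted on the ratio scale (matching the Δ definition);
  batches on the logit scale (matching the correction model).
- **Planted truth**: 200 standalone DMCs (|Δ| = 0.30; 70% hypomethylated on
  background sites, 30% hypermethylated inside islands, so each direction has
  the headroom to express itself), 10 DMR clusters of 10 *consecutive* CpGs
  with gaps ≤ 200 bp (Δ = −0.25 on all member sites — real DMRs affect every
  CpG in the interval; planting on interleaved subsets would seed the runs
  with sign-random background sites and shatter them), and 12 case-exclusive
  UMR blocks of 20 CpGs at level 0.02 carried by ⌈0.8 × 14⌉ = 12 cases and
  no control. Truth lists every differential site (standalone, cluster and
  block members) with its expected Δ.
- **Determinism**: one `numpy` Generator seeded once; outputs are
  byte-identical across reruns.

What it does **not** emulate: sequence-context CpG spacing, read-level
errors, incomplete conversion, cell-type mixtures, correlated biological
noise along the genome, or hg38 coordinates. Passing recovery tests
therefore demonstrate that the statistical machinery is correct under its
own assumptions, not that the thresholds are optimal on real methylomes.

## Problem sizes

The test and acceptance workloads are sized for a laptop: the default preset
(~20,000 sites × 20 samples) runs the full pipeline in about one second;
null-calibration suites use 10–20 cohorts of 5,000 sites; the Wallenius
sampling oracle uses 10⁵ draws. The whole suite completes in well under a
minute of compute plus simulation time.

## Known limitations

- Student's *t* on ratios ignores coverage heterogeneity between samples; a
  beta-binomial model (out of scope here) would weight reads, not samples,
  and would remove the boundary-variance artifact noted above.
- The UMR FDR is a permutation stand-in for the segmentation-model FDR of
  HMM-based callers; its null destroys local autocorrelation, which makes it
  mildly conservative for long regions.
- The neighbour combination is unweighted; no autocorrelation adjustment is
  made within the 200 bp window.
- Enrichment ships no ontology; category maps are user-supplied flat files.
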