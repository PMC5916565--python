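# Methods notes

This note records the models behind `hsnsig`, the conventions adopted where
a published description leaves the details open, and what the synthetic
benchmarks do and do not demonstrate.

## PWM scanning with consensus filtering

A family's binding preference is a position probability matrix estimated
from aligned functional sites with a pseudocount (default 0.1 per base,
preventing −∞ log scores from the small site collections typical of
functional-site compendia).  Scores are sums of per-position
log-probabilities, min–max normalised between the worst and best sequence
attainable under the matrix, so the 70% threshold is a *relative score* in
[0, 1].  A log-odds or quantile scale would also be defensible; the
min–max relative score was chosen because it is the common convention for
"percent of maximum" PWM thresholds and is scale-free across families of
different widths.

The exact IUPAC consensus filter is applied to the matched window at any
offset, not to a fixed sub-range of the PWM, because the filter's purpose
is specificity of the matched sequence as a whole.  Both strands are
scanned by default; a window matches on the minus strand when its reverse
complement passes both filters, and coordinates are always reported on the
plus strand, 0-based half-open (BED-compatible).  Note that the Insm
consensus is its own cross-strand mirror pair (`CCSCWNNM` =
revcomp(`KNNWGSGG`)), so either spelling yields identical both-strand
match sets — a property the test suite asserts.

Windows containing N are skipped rather than scored (their probability is
undefined); the scanner logs how many were skipped.  Scanning requires a
strictly positive matrix; a zero-pseudocount PWM can be built and
inspected but not used for scanning.

Performance: regions are concatenated with N spacers and each
model/strand is scanned in one vectorised pass; the consensus filter (a
cheap integer test, typically passing < 1% of windows) runs first and only
candidate windows are scored.  The result is bit-identical to the
per-window definition, which the oracle tests check exhaustively.

## Signature windows and tiers

Candidate windows are *match-bounded*: every interval from one match start
to another match end with span ≤ `L_max` (600/700/800 bp allowed, default
700 bp, the mid-size that maximised class contrast in the motivating
analysis).  Each interval is labelled by the exact number of distinct
families with a match fully inside it; intervals with ≥ `k_min` (default
4) families are kept, grouped by that exact count (the tier), and
overlapping or bookended intervals are merged within a tier.  Two
conventions matter:

- A merged window keeps its group's tier even when the union of its
  constituents' family sets is larger; tiers answer "where are the
  windows with exactly k motif types", while gene-level classes are
  cumulative ("≥ k"), giving the nested proportions cascade.
- Merged windows may exceed `L_max`; the length cap constrains the
  initial search, not the merged report.
- Windows never span distinct regions of one gene: upstream and intronic
  sequences are separate coordinate systems.

Gene classification is the maximum tier over all the gene's regions;
genes with no window at any tier are unclassified (`None`).  Class
prevalence (e.g. neuronal vs non-neuronal genomes) is compared with
Pearson's chi-squared on the 2×2 table, without continuity correction.

## Matched-resampling enrichment

The null model for "the reference set carries the signature more often"
must control for regulatory-region length, since longer regions
accumulate windows by chance.  Null sets (default 10,000 sets of 96
genes) are drawn by rejection sampling from the non-reference,
has-ortholog universe until a two-sided Mann-Whitney U test of total
regulatory length (upstream + intronic) against the reference gives
p > 0.05.  A configuration flag switches to the stricter two-test variant
(upstream and intronic lengths each matched); the single-total test is the
default because the two components are strongly correlated with the
acceptance rate and one joint criterion matches the "similar in length,
on average" requirement with fewer rejections.  Sampling failure within
the attempt cap (default 1,000 per set) raises an error naming the failed
criterion rather than silently relaxing it.

The enrichment percentile uses the mid-rank convention
(`100·(#below + ½·#equal)/n_sets`), avoiding degenerate 0/100 percentiles
on tied null proportions; significance is percentile > 95.  The
Mann-Whitney statistic uses exact enumeration for untied samples of ≤ 8
per group and the tie-corrected normal approximation otherwise (SciPy's
implementation behind the module's own surface).

## Conservation filter

A signature of tier *t* is conserved when *every* ortholog in *every*
comparison species has a window of tier ≥ *t* under identical scan
parameters.  The strict "every ortholog" reading is the default; a flag
selects the weaker "at least one ortholog per species" reading, since
phrasing like "found in all orthologous genes" is genuinely ambiguous
between the two.  Genes with no orthologs are non-conserved by definition
and excluded from conservation-filtered enrichment universes, mirroring
the ortholog requirement of the null-set sampler.  Conservation tests
window *presence*, not sequence alignment — functional enhancer windows
are known to turn over at the sequence level while preserving content.

## Homology clustering with multiscale bootstrap

Mouse CPM values are called present strictly above 19 CPM (a value of
exactly 19 is absent); the threshold yields roughly a third of genes
present per sample under the generator's marginal, matching the expressed
fraction expected of a neuronal transcriptome, and the clustering is
robust over a wide threshold range.  Worm matrices drop pan-neuronal
genes and columns with fewer than 30 present genes (exactly 30 is kept).
Worm genes map into mouse gene space through the ortholog table: no
ortholog → dropped, k orthologs → k duplicated rows, never-expressed
genes dropped.

Distance between cell-type columns is the asymmetric binary (Jaccard)
distance — mismatches over the union of presences — so shared absences
carry no signal; two all-zero columns are defined to be at distance 0
(logged; unreachable after column filtering).  Trees are UPGMA (average
linkage) with a deterministic tie-break: among equal-distance pairs, the
lexicographically smallest pair of minimum leaf labels merges first, so
trees are identical across platforms and input orders.

Cluster support follows the multiscale bootstrap: genes are resampled
with replacement at scales r = 0.5, 0.6, …, 1.4 of the row count
(`nboot` replicates per scale, default 10,000), and each base-tree
cluster's replicate frequency `BP_r` is recorded.  BP is the frequency at
r = 1; AU extrapolates `z_r = Φ⁻¹(1 − BP_r)` through the weighted
least-squares fit `z(r) = v·√r + c/√r`, giving `AU = 1 − Φ(v − c)`.
Numerical conventions:

- `BP_r` is clamped to `[1/(2·nboot), 1 − 1/(2·nboot)]` before the probit;
  a cluster at frequency 1 (or 0) at *every* scale short-circuits to
  AU = 1 (or 0) directly.
- WLS weights are the delta-method weights on the probit scale,
  `w_r = nboot·φ(z_r)²/(BP_r(1−BP_r))`.  Weighting by the inverse
  variance of `BP_r` alone would up-weight exactly the clamped,
  least-informative scales; the φ² factor is what makes the weight the
  inverse variance of `z_r` itself.
- Replicate trees are built with SciPy's average-linkage implementation
  for speed, on a canonical (label-sorted) column order so that support
  values are exactly invariant under column permutations of the input;
  the package's own deterministic UPGMA builds the reported base tree and
  is cross-checked against brute force in the tests.
- A scale grid without r = 1.0 reports BP from the nearest scale with a
  warning; a single-scale grid reports BP but no AU.

The anchored control replaces the reference cell type's profile with
random sets of 96 expressed genes that always include the four
serotonin-pathway genes (*tph-1*, *bas-1*, *cat-1*, *cat-4*), and re-runs
the analysis; the planted profile should, and random profiles should
rarely, land nearest to the mouse samples.

## Synthetic benchmarks: what they emulate

The genome generator draws per-gene upstream and intronic backgrounds
from an order-0 model at GC 0.36 (worm-like), with log-normal lengths
(upstream median 800 bp, σ = 0.5; intronic median 300 bp, σ = 0.7 —
compact, *C. elegans*-scale regulatory regions).  With per-class
probability (reference 0.40, neuronal 0.25, non-neuronal 0.10; universe
average ≈ 0.15) a full six-family cluster is planted in a random window
of ≤ 700 bp: one site per family, sampled from the family PWM conditioned
on passing both the score and consensus filters, on random strands,
non-overlapping.  Ortholog tables cover four species (multiplicity
0/1/2 with probabilities 0.1/0.8/0.1); a planted cluster is copied — as a
fresh instance on fresh background, since the method tests presence, not
sequence identity — into a species' orthologs with per-class probability
(0.9/0.8/0.4), and a gene is conserved in truth only when all four
species received copies in all their orthologs.  The reference class uses
the same length distribution as the universe, so the length-matching
sampler operates at its unconditional ≈ 95% acceptance rate; a scale knob
exists to study mismatched references, which drive the sampler to its
explicit infeasibility error.

The expression generator plants one worm cell type whose 200-gene profile
overlaps the mouse raphe-like expressed set at fraction 0.8 (through the
ortholog map), among 39 unrelated worm neurons with random profiles, six
raphe-like CPM samples, two cortex-like controls, and ten pan-neuronal
genes that the filter must remove.  CPM values are two-component
log-normal (expressed median 100, absent median 2, σ = 1 on the log
scale).

What passing tests on these benchmarks shows: the scanning, window,
resampling, conservation and bootstrap machinery is correct, calibrated
(5% false-positive rate under the null) and powerful under realistic
signal strengths.  What it does not show: anything about real WormBase
genomes or real raphe RNA-seq — real backgrounds are not order-0, real
binding sites are not PWM draws, real ortholog tables are incomplete and
biased, and real expression calls are noisier than a two-component
log-normal.  Headline percentages from the synthetic genome (e.g. ~29% of
genes with a six-motif window) characterise the benchmark, not any
organism, although their nested structure mirrors the genome-scale
behaviour of the method.

## Problem sizes

Defaults follow the study conditions (10,000 null sets of 96; nboot
10,000; scale grid 0.5–1.4).  The test suite and the acceptance script
scale down where iteration count, not per-run size, carries the
statistical content: enrichment calibration uses 500 replicate
experiments of 200 null sets; power uses 50 replicate genomes of 2,000
genes with 200 null sets each; cluster support checks use nboot = 2,000,
where Monte-Carlo error on BP is below 1.2 percentage points.  These
sizes are the package's own choices for routine verification; all
full-size defaults remain one argument away.

## Known limitations

- The AU extrapolation inherits the usual small-`nboot` instability for
  clusters with `BP_r` near 0 or 1 at few scales; the clamping rule keeps
  it defined but saturated values (exactly 0 or 1) should be read as
  "beyond Monte-Carlo resolution", not as exact probabilities.
- Rejection sampling of matched sets can be slow or infeasible when the
  reference's length distribution is extreme relative to the universe;
  the error is explicit, and the two-test variant tightens matching at a
  further acceptance-rate cost.
- The window search is exact but quadratic in matches per region; for
  regions with thousands of matches (relaxed thresholds) a sweep
  implementation would be preferable.
- Ortholog relations are consumed as given; no attempt is made to infer
  or deduplicate them beyond the declared species list.
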