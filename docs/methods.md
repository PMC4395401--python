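# Methods

This note records the models, parameter choices, and numerical decisions
behind `arraymap`, in the order data flows through the pipeline.

## Population model

A RIL population is simulated as a single F1 between two fully homozygous
parents, self-pollinated for `generations − 1` rounds (`generations = 7`
models an F7:8 population: seventh-generation plants, eighth-generation
seed).  Meiosis follows the Haldane model — no crossover interference — so a
gamete carries a Poisson number of crossovers with mean equal to the
chromosome length in Morgans, at positions uniform on the genetic map.  Each
selfing round draws two independent gametes per lineage.  Per locus the
selfing transition is AB → ¼ AA + ½ AB + ¼ BB with homozygotes breeding
true, giving the genotype expectation `((2^(t-1)−1)/2^t, (1/2)^(t−1),
(2^(t-1)−1)/2^t)`; at t = 7 this is exactly (63/128, 2/128, 63/128), and
`expected_ril_probs` computes it by iterating the recursion with exact
rational arithmetic.

Marker physical positions are uniform per chromosome (strictly increasing);
genetic positions are proportional to physical positions unless hotspots
(local rate multipliers, total length preserved) are configured.  Default
chromosome sizes follow a seven-chromosome cucurbit-like genome (~192 Mb,
~599 cM) with ~2,000 markers allocated by physical length and 120 RILs.

**Segregation distortion.** When an SDR is configured, viability selection
acts at the marker nearest the interval midpoint *in every selfing
generation*: offspring survive with relative weight `w : sqrt(w) : 1` for
AA : AB : BB (rejection sampling).  Compounding over the series, weight 3
yields p(AA) − p(BB) ≈ 0.45 near the anchor — the magnitude of the one-sided
SDRs such arrays detect — decaying along the chromosome by hitchhiking.  The
standalone `apply_segregation_distortion` operator instead performs a single
round of viability-weighted resampling of whole lines on a realized
population, which is the right tool for post-hoc what-if analyses; its
effect is weaker and noisier than in-breeding selection, which is why the
simulator embeds selection in the breeding loop.

## Signal model

Hybridization signals live on the log2-intensity scale: probe
(snp, allele, strand) on array j measures
`center[genotype, allele] + probe_effect + array_effect + noise`, emitted as
linear intensities `2^x`.  Defaults: cluster centers AA (12, 7),
AB (10.5, 10.5), BB (7, 12); noise SD 0.3; probe-affinity SD 2.0; array SD
0.2.  The probe-affinity spread is deliberately the dominant variance
component: on real hybridization platforms sequence-dependent affinity spans
orders of magnitude, and it is what makes the intensity *distributions* of
parent, F1 and segregant arrays comparable — the property quantile
normalization relies on.  (With small probe effects the F1 arrays, whose
probes all sit at intermediate intensity, would be visibly warped by rank
mapping; the generator therefore treats large probe effects as part of the
study conditions, not a tuning knob.)

Training hybridizations follow the 6 + 5 + 5 design (parent A, F1,
parent B), sharing probe effects with the test arrays.  Each training point
is drawn from a wrong cluster with probability `miscluster_rate`
(default 0.01, giving ≈ 1% rejected SNPs and ≈ 14% one-off GTS SNPs —
direction-comparable to the real arrays, which reject more and see ~10%
one-off).  Intensities are missing independently at `missing_rate`
(default 0.002).  Optional spatial defects multiply contiguous grid blobs of
probes by a factor (0.15 or 4) on randomly afflicted arrays; the probe→grid
layout is randomized, as vendors do.

The pileup world (for probe design) draws total depth from a lognormal
parameterized so that 90% of rounded depths fall in 8–39 reads (continuity-
corrected quantile matching), with ~1 candidate SNP per 700 bp, 95% unique
mapping, and base qualities uniform on 15–44.

## Preprocessing

Order: log2 → quantile normalization between arrays (training and test
jointly) → per-probe median centering → spatial-defect masking → median
polish.  Quantile normalization uses mean-of-order-statistics with mid-rank
tie handling; missing entries are excluded from ranks and restored as
missing; unequal column counts are handled by interpolating each column's
quantile function onto a common grid.  Both normalization and centering are
idempotent.

The spatial filter compares each probe with the median of its
(2·radius+1)² grid neighborhood (radius 3) and flags residuals above
k · local MAD (k = 5).  Because genuine slide defects — scratches, bubbles —
are spatially contiguous while biologically extreme probes are scattered by
the randomized layout, flagged probes are only masked when they form a
4-connected cluster of ≥ 5 grid cells; this keeps the false-positive rate on
defect-free arrays at zero without desensitizing the filter to real blobs
and scratches.

Replicate summarization runs Tukey median polish on each (SNP, allele)
2 × n_arrays strand-replicate matrix (at most 10 iterations, convergence when
the total absolute residual change drops below 1e-8; NaN-tolerant and
batched across SNPs).  The per-array summary is the fitted overall plus
column (array) effect, which removes the strand effect and is robust to a
single aberrant replicate; an entry with no surviving replicate is masked.

## Genotype calling

Per SNP, k-means with k = 3 partitions the 16 training points, initialized
deterministically at the expected-label group means (removing seed
sensitivity on 16-point problems) and run as a batched Lloyd iteration
across all SNPs (100-iteration cap; sklearn's KMeans is the independent
cross-check in the tests).  Clusters take the majority expected label; a SNP
is rejected when clusters are empty, two clusters claim one label, fewer
than 3 points per label survive masking, or > 1 point disagrees with its
expected label.  Exactly one disagreement is a "one-off" good training set,
matching the rule that one misclustered signal is tolerated.

Cluster covariances from 5–6 points are near-singular, so each is shrunk
toward the pooled diagonal: `Σ ← (1−λ)Σ + λ·diag(pooled variance) + 1e-9·I`
with λ = 0.1.  Calls use Mahalanobis distances to the three cluster means:
d0 to the nearest (the tentative call), d1 to the nearest other; confidence
= d1/(d0+d1) ∈ [0.5, 1] for any call, and calls with confidence ≤ 0.6 become
no-calls (the same 0.6 also defines "low confidence" in the marker filter;
the threshold is exposed because applying it at call time versus filter time
is a reporting choice).

## Marker and sample filtering

Applied in order (the order affects the counts and is therefore explicit):

1. **Redundancy dedup** — markers with byte-identical call vectors
   (no-call pattern included) collapse to the member with the largest
   minimum pairwise Bhattacharyya distance among its three clusters
   (`D = ⅛ δᵀΣ̄⁻¹δ + ½ ln(det Σ̄ / √(det Σ₁ det Σ₂))`); ties keep the
   smallest id.  Collapsed members are re-attached to their
   representative's bin after mapping.
2. **Low confidence** — per-SNP count of calls with confidence ≤ 0.6;
   drop SNPs above median + 1 raw (unscaled) MAD.
3. **Segregation** — goodness of fit against the F_t expectation with
   Bonferroni correction at α = 0.05.  With every expected cell ≥ 5
   (Cochran's rule) a 3-category χ² is used.  Below that — always the case
   for the AB cell at realistic sample sizes, where the χ² tail is inflated
   by an order of magnitude — the test splits into an AA-vs-BB χ²
   (reduces to (nAA−nBB)²/(nAA+nBB) since pAA = pBB) plus an exact one-sided
   binomial test for heterozygote excess, Bonferroni-combined as
   `p = 2·min(p_hom, p_het)`.  Measured family-wise error under the exact
   null (2,000 SNPs × 120 RILs): ≈ 0.03.
4. **Sample QC** — drop samples whose heterozygous fraction (among calls)
   exceeds 0.2; drop samples whose homozygous calls are under 0.15 *of all
   markers* (the all-marker denominator is what lets the rule catch
   no-call-heavy, uninformative samples — with a calls-only denominator it
   would duplicate the het rule); after refinement, drop samples with more
   than 10 no-call regions (maximal runs of consecutive no-calls, summed
   over linkage groups).

## Map construction

Recombination evidence uses only homozygous call pairs (heterozygotes are
rare, 2/128, and transient): observed fraction R = discordant/informative,
with pairs under 10 informative samples treated as unlinked.  The selfed-RIL
correction inverts the crossover accumulation of repeated selfing.  Two
forms are provided: the classic Haldane–Waddington limit `r = R/(2(1−R))`,
and a generation-aware inversion (default, t = 7) of the exact curve
`R_t(r)` computed by a two-locus selfing transfer matrix (16 ordered gamete-
pair states; a meiosis emits parental haplotypes with probability (1−r)/2
each and recombinants with r/2 each).  At t = 7 the observed fraction runs
≈ 11% below the Haldane–Waddington limit for tight linkage — selection of
the limit formula would bias map lengths down by the same amount — and the
recursion converges to the limit as t grows (verified against an independent
forward simulation).

Grouping connects markers whose two-locus independence test rejects at
p < 1e-10 (missing-call fraction ≤ 0.15 required; groups under 2 markers set
aside), then takes connected components.  The test is a 2×2 χ² on the
homozygous table with an exact fallback — the one-sided positive-association
hypergeometric tail, appropriate because linked RIL markers are in coupling
phase — used when any expected cell is < 5 or when the χ² p lands within a
few orders of magnitude of the cutoff, where the Pearson far-tail is
unreliable.

Ordering minimizes the sum of adjacent meiotic recombination fractions:
exact enumeration for groups of ≤ 7 markers, greedy chain construction over
ascending pairwise r followed by 2-opt segment reversals for larger groups.
All ties break by ascending marker id and the orientation is canonicalized
(first id < last id), so output is independent of input order.  Adjacent
markers with zero observed recombinants merge into bins; bin positions
accumulate Haldane distances `d = −50·ln(1−2r)` between boundary pairs.

Recovered map length on the benchmark design (1 chromosome, 100 cM, 200
markers, 120 RILs) is unbiased with ≈ 7% relative SD per population — the
irreducible Monte-Carlo noise of the total breakpoint count — so recovery
checks average five replicate populations.

## Refinement

Per sample along each linkage group, two rules iterate to a fixpoint
(region rule first, then locus rule; almost always one or two passes,
capped at 10 because a locus pass can create a new mosaic stretch):

* **Region rule** — a maximal stretch of singleton calls (every locus
  differing from its predecessor) spanning ≥ 12 loci becomes no-call.
* **Locus rule** — a locus differing from at least one immediate neighbor
  is re-examined: if either 6-locus flank is uniformly the locus's own call
  it stands (clean recombination breakpoints survive); if both flanks are
  uniform with a common other call, the locus takes it; otherwise it becomes
  no-call.  Loci within 6 of a chromosome end are never modified, and a
  locus bordering a no-call is left alone (the uncertainty boundary is not
  advanced — this is also what makes the pass idempotent).

"12 or more different consecutive calls" is operationalized as the singleton-
run reading (a mosaic segment of ≥ 12 loci with no two adjacent equal); the
alternative reading (12 call-switches across longer blocks) would also wipe
legitimate short haplotype blocks.  Refinement may erase genuine double
recombinants and gene-conversion-like events; no attempt is made to
distinguish them.

## Genome scans

* **Local recombination rate** — markers whose genetic order contradicts the
  physical order are removed first (largest consistent subset via longest
  nondecreasing subsequence after rank-correlation orientation); cM is
  Lowess-smoothed against Mb (span 0.1) and each 5-marker window's
  least-squares slope is reported in cM/Mb, clamped to 1e-6 before log10
  (log10 is the reporting scale).
* **Segregation-distortion scan** — per marker, Δ = p(AA) − p(BB) and the
  χ² statistic (nAA−nBB)²/(nAA+nBB) under the equal-frequency null;
  Benjamini–Hochberg step-up at α = 0.05; SDR intervals are maximal runs of
  ≥ 3 consecutive significant markers (physical order) sharing a favored
  allele.  The ≥ 3 run rule is this package's operationalization of
  graphically delimited regions.  A cubic smoothing spline of Δ versus
  position (generalized cross-validated smoothing parameter) is attached for
  reporting only.
* **Collinearity** — per linkage group, R² of cM on Mb (orientation resolved
  by the rank-correlation sign) and the fraction of markers whose group
  matches their majority chromosome.
* **Bin polymorphism** — a marker is polymorphic when non-parental
  accessions carry ≥ 2 distinct non-missing genotypes; a bin is covered when
  any member is polymorphic; non-polymorphic markers sharing a bin with a
  polymorphic one are "replaceable".  The accession generator forces a
  configurable fraction of markers monomorphic (default 0.40, yielding
  ≈ 47% effectively monomorphic markers) without haplotype structure, so
  coverage numbers are illustrative, not population-genetic predictions.

## What the generator does and does not emulate

The generator reproduces the statistical structure the pipeline's decisions
rest on: selfing-series genotype frequencies, no-interference crossovers,
Gaussian cluster geometry with shared probe/array effects, misclustered
training points, missing data, contiguous spatial defects, depth-calibrated
pileups.  It does not model crossover interference, background/dye bias,
cluster asymmetries (e.g. allele-specific cross-hybridization), genome
mis-assembly or paralogy (beyond a uniqueness flag), linkage disequilibrium
structure in unrelated accessions, or genotype-dependent missingness.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under their stated assumptions, not performance on any real
array.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` use desk-scale designs chosen to
make each check's error model valid: ~50 cM locus spacing for the
heterozygosity check (so the binomial standard error applies to
near-independent loci), 2,000 SNPs × 120 samples for calling accuracy,
five replicate populations for map-length recovery, 200 null replicates for
the error-control estimates, and 20 seeded replicates for SDR recovery.
Every expected value asserted in the tests is computed by an independent
oracle (closed form, exhaustive enumeration, literal re-implementation, or
forward simulation) rather than taken from the implementation under test.
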