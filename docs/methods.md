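# Methods

## The experimental design being modelled

A single outbreeding population (a synthetic cultivar with many parents,
hence little structure and fast LD decay) is phenotyped for a quantitative
trait — days to elongation (DTE), right-censored at the end of the
observation window for plants that never elongate. The two phenotypic
extremes (52 earliest, 52 latest elongating) are selected, each split at
random into three replicate DNA pools of 17–18 individuals, and each pool
sequenced by reduced-representation GBS. Pooling makes the reference-allele
frequency (RAF) per marker per pool the observable; the analysis asks at
which markers the early and late groups differ more than replicate-pool
noise allows.

Two marker types are analysed: biallelic SNPs, and GBS-locus haplotypes
(HTPs) — short 0/1 strings over the polymorphisms within one GBS locus,
which can carry more than two alleles per locus. Haplotype variants are
tested one-vs-rest as pseudo-biallelic frequencies; a locus is significant
if any of its variants is.

## Differentiation tests

**Replicate F_ST test.** Each of the six pools is contrasted with the
gamete-weighted mean frequency of the three opposite-phenotype pools.
Pairwise F_ST = (mean(q²) − mean(q)²) / (mean(q)(1 − mean(q))) with gamete
weights (34 or 36 per pool; 104 for a three-pool aggregate), set to 0 when
the weighted mean frequency is 0 or 1 (no variance to apportion; this
extends the absent-in-both convention symmetrically to fixed-in-both).
X² = 2N·F_ST is referred to χ²(1), 2N being the summed gametes of the two
compared units (e.g. 34 + 104 = 138). A marker is significant at level P
only if all six comparisons are significant and the three early pools all
sit on one side of the late mean while the three late pools sit on the
other. The FDR at level P is estimated as (l·P³/d)² — the cube and square
encode the all-replicates and both-directions requirements under an
independence heuristic — and the working P-level is the largest grid point
(log-spaced 1e-8…1e-1, 50 points) with estimated FDR ≤ 0.05 and d > 0.

**Error-variance test.** Z² = (q̄_L − q̄_E)² / (V1_L + V1_E + V2_L + V2_E)
referred to χ²(1), with q̄ the gamete-weighted mean over a group's three
replicate pools, V1 = q̄(1−q̄)/(2·52) the variance from sampling 52
individuals per group, and V2 = σ²_rep/3 the observed between-replicate
variance (unbiased n−1 estimator over the three pool frequencies — the
natural choice; with three replicates the denominator is 2). A zero
denominator yields Z² = 0 (p = 1) when the group means agree and +∞ (p = 0,
flagged degenerate) when they differ, which occurs only at fixed opposite
frequencies. FDR(P) = l·P/d with the same grid and target.

**Weights.** All weighted means use gamete counts (2 × individuals). The
alternative — weighting by read depth — would couple the test statistic to
sequencing luck; gametes are the sampling unit the χ² calibration assumes.
For the χ² sample size of a three-pool contrast unit we use the full
summed gametes (≈104) rather than an effective size: the two compared
"populations" are the focal pool and the whole contrasting group.

**BayeScan.** Interoperation only: frequencies become absolute allele
numbers per group (round(q·gametes) per pool, summed over the three
replicates; totals 104), written in BayeScan 2.1 two-population format, and
`*_fst.txt` results are mapped back to marker ids by export order and
thresholded on the q-value column. The MCMC itself is external.

## Marker filters

SNP filters, in order, per pool then across pools: (i) delete records whose
reference base is not A/C/G/T; (ii) set a pool missing when both of its
observed alleles differ from the reference or its ref+alt read sum is
below 30; (iii) zero an allele (count and frequency) whose presence
posterior is below 0.95, recomputing RAF from the remaining counts;
(iv) set a pool missing below 27 residual reads; (v) drop records with more
than two distinct remaining alleles across the six pools of a library;
(vi) keep records with RAF within [0.05, 0.95] — bounds inclusive, matching
the ≥-style haplotype threshold — in at least one pool and data in all six.
Missingness is an explicit per-pool flag, not a sentinel value. The
across-pool stages operate within one library's table at a time. Haplotype
loci drop variants never exceeding 5% frequency in any pool (frequencies
renormalised), then require ≥2 surviving variants and ≥30 reads in every
pool. Every stage logs entering/removed/surviving counts, which are
conserved by construction.

Because a wide RAF record carries one global ref/alt pair, two optional
per-pool columns make the rarer filter conditions representable:
`{pool}_both_nonref` (stage ii's both-alleles-non-reference case) and
`{pool}_alt_base` (pool-wise alternative base for stage v's allele
accounting). Absent columns default to the benign case.

## The synthetic-data generator

`poolbsa.sim` emulates the statistical structure the tests assume, not the
sequencing chemistry:

* **Founder panel** — markers spread over 7 chromosomes (~420 Mb genome
  scale), founder alternative-allele frequencies uniform in [0.05, 0.95];
  an optional fraction of markers on unplaced scaffolds.
* **Genotypes** — Hardy–Weinberg dosages, free recombination between
  markers by default (the tests are single-marker; the population modelled
  has low LD). An optional block-LD mode draws gamete alleles from a shared
  uniform per block for LD-sensitivity experiments.
* **Trait** — DTE = baseline + Σ effect·dosage + Gaussian noise; plants
  beyond the censor day are non-elongating and excluded. Defaults
  (baseline 82 d, noise SD 10 d, censor at day 94, four QTLs of ±8 d at
  founder frequency 0.5) give ≈22% censoring — the 146-of-672 design rate —
  and a ~23–94 d DTE span. A Gaussian trait cannot reproduce the skewed
  extreme-group means of real data (see limitations).
* **Sequencing** — depth per marker and pool is negative binomial
  (mean 100, dispersion 5; variance = mean + mean²/dispersion), optionally
  floored at a minimum when emulating post-filter data; the 30-read filter
  threshold is the study's only stated depth constraint, so mean and
  dispersion are free parameters set to a realistic mid-depth GBS profile.
  Alternative-allele reads are binomial with success q(1−e) + (1−q)e,
  e = 0.001 per-read error by default. Allele-presence posteriors use a
  binomial absence model — 1 − P(≥ observed reads | error only) — standing
  in for the upstream Bayesian caller; only its thresholding behaviour
  matters downstream.
* **Haplotypes** — loci group k = 2 consecutive SNPs; within a pool,
  variant probabilities assume linkage equilibrium between the grouped
  SNPs (products of per-SNP frequencies) and per-pool counts are
  multinomial in the locus depth. Read-stack delineation of real GBS data
  is not modelled.
* **Annotation** — a toy GFF3 writer plants genes inside and outside
  ±50 kb marker windows and returns the truth list.

Ground truth (per-pool and per-group true allele frequencies, QTL flags)
is emitted alongside the tables; the true pooled frequency equals the mean
member dosage / 2 by construction.

## Loci and candidate genes

Significant markers cluster into loci by single linkage at 100 kb — all
multi-marker loci reported in the motivating study span < 1 kb, so any
join distance in that range reproduces its groupings. A locus is named
`chrom_Mb` with the first marker's position in megabases rounded half-up
to two decimals; unplaced scaffolds keep their id and coordinate. The
candidate-gene window is ±50 kb around the locus' marker span (not each
marker separately), 1-based inclusive; any 1-bp overlap counts, and genes
are ordered by distance to the nearest anchor marker. BED exports are
0-based half-open.

## Numerical and interface choices

* Ties in extreme selection break by individual index (stable sort);
  pool assignment partitions a group with sizes differing by at most one.
* All randomness flows through `numpy` `SeedSequence` spawning, so a run
  is byte-reproducible from one seed.
* The FDR scans return an explicit empty set (with a warning) when no
  grid level attains the target with d > 0.
* The differentiation stage is exposed as a model/results pair
  (`PoolContrast.fit()` → `ContrastResults` with `summary()`), which fits
  its statistical character; simulation, filtering and annotation remain
  plain functions orchestrated by `RunConfig`/`run_pipeline`.

## Validation studies and their scales

The test suite and `scripts/acceptance.py` run replicated whole-design
simulations: null calibration at 20,000 markers (20 seeds in the suite,
10 in the script), and power/stringency at 2,000 markers with three
planted QTLs of 15 d (~1.5 environmental SD per allele copy), which under
10%-tail truncation selection typically push the realised between-group
frequency difference past 0.5. These sizes keep a full run within a few
minutes on one CPU while leaving Monte-Carlo error well below the margins
being asserted.

## Known limitations

* **The (l·P³/d)² FDR heuristic is not calibrated at moderate depth.** The
  package's own null study shows it: with no QTLs planted, the
  error-variance test declares nothing (empirical FDR 0), but the
  replicate F_ST scan settles at P ≈ 0.04–0.07 and declares tens of
  markers per 20,000 — all false. Two ingredients combine: read-depth
  sampling adds frequency noise that the gamete-count 2N does not model
  (≈1.3× χ² inflation at depth 100), and the six comparisons share the two
  group means, so the P³ independence assumption understates the joint
  null rate. At depths ≥ 500 the same scan returns empty sets. In
  practice the test should be read as a ranking device whose false
  discoveries are removed by intersection with the error-variance test
  (the consensus is empty under the null), not as a calibrated FDR
  procedure at GBS depths.
* The Gaussian trait model reproduces the censoring rate and selection
  structure but not the skewed DTE distribution of real data; simulator
  power estimates are therefore indicative, not forecasts for any real
  population.
* Within-pool haplotype variant frequencies assume linkage equilibrium
  between grouped SNPs unless the block-LD genotype path is used; real GBS
  haplotypes are maximally linked within a read.
* Filters operate on one library's six-pool table at a time; cross-library
  allele harmonisation (stage v across libraries) is out of scope, as is
  everything upstream of the frequency tables (alignment, SNP calling,
  read-stack delineation) and BayeScan's MCMC internals.
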