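# Methods

`rhythmhic` analyses temporally resolved chromatin-conformation data from a
circadian experiment: Hi-C contact matrices, promoter-capture interaction
tables and RNA expression sampled at four Zeitgeber times (ZT0, ZT6, ZT12,
ZT18; ZT0 = lights on), with three Hi-C and four RNA replicates per
timepoint. This note documents the models, the numerical choices, what the
synthetic generator emulates, and the limits of what passing tests
demonstrate.

## Contact-matrix normalisation

A symmetric binned matrix is balanced by a diagonal scaling `B = D M D`
(iterative symmetric correction, multiplying biases by sqrt(target/rowsum)
per sweep) until all unmasked row sums agree within a relative tolerance
(default 1e-6, configurable; all-zero rows are masked). The downstream
statistics depend only on the equal-row-sum contract, not on the particular
balancing solver. The observed/expected transform divides each entry by the
mean of its diagonal offset over unmasked bins; diagonals with zero expected
value are masked. By construction every diagonal of an O/E matrix has mean 1.

## A/B compartments and oscillatory chromatin compartments (OCCs)

PC1 is the eigenvector of the largest eigenvalue of the Pearson correlation
matrix of the O/E map, computed per chromosome at 100-kb bins. Its sign is
anchored so that PC1 correlates positively with an activity covariate (an
active-chromatin coverage track; the synthetic runs use planted gene
density). A-compartment: PC1 > 0; exact zeros count as A and carry a tie
flag. Replicate tracks are each oriented independently against the
covariate; merged-replicate matrices (summed counts) give the per-timepoint
reference track.

A bin is oscillatory when (i) a one-way ANOVA of its replicate PC1 values
grouped by timepoint is significant after Benjamini-Hochberg correction
across bins (default alpha 0.05) and (ii) its merged-track sign differs
between at least one pair of timepoints. Both conditions are required:
large same-sign PC1 changes are not compartment switches. Adjacent
oscillatory bins sharing the same 4-letter category string (e.g. `AABA` = A
at ZT0/6/18, B at ZT12) merge into OCC regions. Bins with missing replicate
values are skipped and counted.

## TADs

The insulation score of bin `i` is the mean raw (or balanced) contact count
in the square `[i-w, i) x (i, i+w]`, with `w = window/bin_size` (default
window 200 kb on 50-kb bins); bins within `w` of a chromosome end are
undefined. Boundaries are local minima of the score below a threshold;
minima are strict against the left neighbourhood and non-strict against the
right, so exact ties resolve deterministically to the leftmost bin. Because
published threshold constants are tied to a particular sequencing depth, the
pipeline's default threshold is the chromosome mean insulation score, which
adapts to depth while remaining deterministic. TADs are the intervals
between consecutive boundaries, kept when 150 kb–1.5 Mb and at least 2 bins,
never spanning masked gaps, and are called per timepoint on merged-replicate
matrices. Two TADs are "shared" between timepoints when one covers strictly
more than 80% of the other's length.

Metaplots aggregate O/E submatrices by the cell-wise median: rescaled-TAD
mode maps each domain (plus flanks of half its length per side) onto a fixed
grid by area-weighted rebinning (5 core bins + 5 flank bins per side by
default); point mode takes the (2k+1)^2 neighbourhood around each feature's
bin. Features too close to a chromosome end, or domains shorter than the
core grid, are skipped and counted.

## Circadian expression

A gene is circadian when its expression differs between at least one pair of
timepoints: per-gene one-way ANOVA on log2(FPKM+1) across the four ZTs,
BH-corrected across genes, q < 0.01 by default. Zero-variance genes get
p = 1. The acrophase is the sampled ZT with the highest mean FPKM (ties take
the smallest ZT and are flagged); diurnal = acrophase in {ZT0, ZT6},
nocturnal = {ZT12, ZT18}. This pairwise-difference rule is deliberate — no
harmonic (cosinor/JTK) fit is attempted, because the classification contract
is "differential between at least one pair of timepoints".

## Circadian TADs

Genes join TADs by TSS (half-open: a TSS at the start belongs, at the end
does not). A cTAD holds >= 1 circadian gene. For TADs with exactly k
circadian genes, the probability that all k share an acrophase under
independent assignment is `sum_i p_i^k`, with `p` the acrophase frequencies
over all circadian genes (switchable to TAD-resident genes only); observed
vs expected (same, not-same) counts are compared with a 1-df chi-square, and
strata with expected counts below 5 are flagged. cTAD enrichment over OCCs
draws equal-size sets of non-cTADs without replacement (z-score and
one-sided empirical p = (1 + #{null >= obs})/(n_iter + 1)); a per-chromosome
paired Wilcoxon is attached when at least two chromosomes contribute.

## Promoter-capture interactome

**Dynamic vs stable.** Counts per (timepoint, replicate) are modelled as
negative binomial with library-size offsets (column totals scaled to mean
1). Dispersion is a 50/50 shrinkage of the per-interaction method-of-moments
estimate toward the 10%-trimmed-mean common dispersion. The likelihood-ratio
test compares per-timepoint means against a common mean (3 df over four
ZTs); the 1-D NB mean MLE is solved by Newton iteration (closed form in the
Poisson limit). Interactions split into near (distance <= 150 kb, the
boundary inclusive) and far regimes — trans contacts fall in "far" — with BH
correction within each regime. Dynamic requires q < 0.05 and |log2 fold
change| >= 1, where the fold change is the max/min per-timepoint normalised
mean (library scaling cancels, so uniformly doubling all counts changes
nothing). All-zero interactions are stable with p = 1.

**Matched permutation null.** Feature enrichment at promoter-interacting
regions counts unique cis other-end fragments overlapping >= 1 feature. Each
null iteration re-places every observed (length L, bait distance D) pair as
an interval of length L whose midpoint sits at +/-D (fair coin) from a bait
drawn uniformly from the bait universe, redrawing out-of-bounds placements
up to 100 times before skipping the pair for that iteration. The empirical
(L, D) joint distribution is therefore preserved exactly. A one-sample
two-sided t-test compares the expected vector against the observed count;
the ratio observed/mean(expected) is reported.

**eRNA wiring, phase coherence, peak contacts.** Oscillatory-enhancer
enrichment resamples equal-size sets from the non-oscillatory enhancer pool
(which must be strictly larger). Phase coherence groups circadian anchors
into diurnal/nocturnal and compares the contacted-element phase
distributions (4 ZT bins for promoters; eight 3-h bins, `floor(h/3)`, for
hourly eRNA phases) by Wilcoxon rank-sum on the phase values in hours. A
contact counts at timepoint t when its interaction score at t reaches the
significance threshold (default 5, the conventional capture-interaction
cutoff); a promoter's peak contact time is the argmax over ZTs (ties
excluded), and the cohort chi-square compares the {0, 6, 12}-hour
offset-to-acrophase distribution against independence of the two marginals.

**Core clock.** The core set is Npas2, Clock, Arntl, Cry1, Cry2, Per1, Per2,
Rorc, Nr1d1, Nr1d2. Per gene: unique significant interactions (union over
ZTs) and the dynamic fraction of its tested interactions. The null draws
equal-size gene sets from circadian non-core genes 100 times; Mann-Whitney
per metric. The resample size defaults to the number of core genes found in
the data and is overridable.

## Promoter-promoter networks

Nodes are bait fragments in >= 1 significant bait-bait interaction; edges
are deduplicated and weighted by summed read support (per timepoint, or
union); inter- and intra-chromosomal edges are both kept. Components with
fewer than 4 nodes can be filtered for presentation. Circadian connectivity
is scored by resampling equal-size non-circadian node sets (induced-edge
z-score and empirical p; the null resamples nodes, not edges) and by a
Mann-Whitney on circadian-circadian edge support versus support of edges
induced by the resampled sets.

## The synthetic generator

`simulate_truth` draws, from one seed: a toy genome (2 x 20 Mb by default),
a restriction-fragment map (mean 4 kb), a plaid A/B pattern in alternating
blocks with a per-bin probability (`occ_fraction`, default 0.2) of switching
category over the day, time-invariant TAD blocks of 300-800 kb, genes placed
at fragment starts (circadian genes preferentially in bins that are A at
their acrophase and inside OCC bins), hourly-phased enhancers (40%
oscillatory, so equal-size resampling nulls stay non-degenerate), and a
planted interaction table. Hi-C counts are Poisson around
`depth * (1+d)^-alpha * (1 + delta*[same compartment]) * (tau if same TAD)`
with defaults alpha=1, delta=1, tau=3, depth=1000 (tens to hundreds of
counts near the diagonal, a realistic desk-scale depth). Capture counts are
negative binomial (gamma-Poisson, phi=0.1) with mean 30; dynamic contacts
are boosted 4-fold at their peak ZT. Expression follows
`baseline*(1 + A*cos(2*pi*(t - phase)/24))` with mean-preserving lognormal
noise (A=1, sigma=0.2). Promoters carry 12 planted contacts each (core-clock
genes ~60% of that, with a doubled dynamic probability so their realised
dynamic fractions land near the 42% vs 27% regime after dilution by their
stable promoter-promoter edges). Enhancer wiring stays within 2 Mb of the
bait.

What the generator does **not** emulate: read-level noise and mapping
artefacts, trans-contact structure (background is uniform), nested sub-TAD
hierarchy, continuous gene phases (gene acrophases sit on the 4 sampled
ZTs), copy-number or GC biases, and the capture pipeline's own background
model (scores are planted, not estimated). Passing recovery tests therefore
demonstrates the correctness and calibration of the statistics under the
generative model, not performance on real sequencing data.

## Numerical choices and degenerate inputs

- Balancing raises after `max_iter` sweeps naming the achieved residual.
- PC1 requires >= 10 unmasked bins and errors on zero-variance correlation
  input; masked bins propagate as NaN and break compartment runs.
- Sub-stream seeds are derived via CRC32 tags, so results are independent of
  Python's per-process hash randomisation; every pipeline stage draws from a
  seed derived from the root seed, making re-runs byte-identical.
- Resampling tests flag degenerate cases (empty feature sets, zero-variance
  nulls, saturated node sets) instead of returning misleading statistics.
- Problem sizes in the default pipeline (2 x 20 Mb genome, 300 genes,
  ~4000 interactions, 100-200 resampling iterations) were chosen so a full
  seeded run completes in seconds on one CPU while every planted structure
  remains comfortably detectable.

## Known limitations

- The eigenvector is computed on whole chromosomes (no per-arm splitting)
  and only PC1 is used; chromosomes where PC1 tracks arm-level features
  rather than compartments would need manual review on real data.
- The TAD caller has no nested-domain model; finer bins yield sub-domains by
  parameter choice, not by a separate algorithm.
- Circular statistics are deliberately simplified: phases are compared as
  hours with ZT0 as origin, which is well-defined within the
  diurnal/nocturnal split but is not a full circular test.
- When planted TADs tile the chromosome, the per-diagonal expected model
  absorbs part of the domain enrichment, capping rescaled-TAD metaplot
  contrast (core/corner ~1.7 at tau=3) below the raw generative factor.
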