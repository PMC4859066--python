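# Methods

## The MACC model

A genomic bin's response to an MNase titration is summarized by the slope
of its normalized fragment frequency against the negated natural log of
the enzyme amount:

```
y_ij = count_ij · 10^6 / L_j · G / 10^8        (normalized frequency)
MACC_i = Σ_j (x_j − x̄)(y_ij − ȳ_i) / Σ_j (x_j − x̄)² ,   x_j = −ln c_j
```

with `L_j` the post-filter library size of titration point *j* and `G` the
total length of the analyzed chromosomes. The log abscissa makes an
exponential titration series (1.5, 6.25, 25, 100 U) nearly equidistant;
negating it makes the sign convention biological: positive slope =
accessible (signal rises as digestion lightens), negative = inaccessible.
The log base only rescales slopes (base 2 multiplies them by ln 2) and is
configurable; natural log is the default.

Assumptions: fragment yield per bin responds monotonically (on the log
scale, approximately linearly) to log enzyme amount over the titration
range; libraries are exchangeable after per-million and genome-size
scaling; a bin's k frequencies are otherwise independent measurements.
With k = 4 points the per-bin Pearson P value (t distribution, 2 df) is
coarse — it is stored for the optional `(1 − P)` significance weighting,
which on well-powered data changes scores very little and is therefore not
applied to final scores by default. A Mann–Kendall alternative is
provided: exact for k ≤ 10 without ties (the null distribution of the
Kendall S statistic is computed by the inversion-count recursion, which
equals full enumeration of the k! orderings), normal approximation with
continuity correction and tie-corrected variance otherwise.

Zero-variance responses get slope 0 with P = 1 rather than an undefined
fit. A bin is *missing* only when it has no mapped fragments at every
titration point (a stricter any-point-zero rule is available); missing
bins stay missing through every downstream stage.

## Fragment processing

Proper read pairs become fragments spanning the outer mate ends. Inserts
outside 50–500 bp are removed (mononucleosome-compatible window; shorter
inserts are sub-nucleosomal debris, longer ones poly-nucleosomal).
Per-position tag counts (each fragment contributes its two sequenced
endpoints, `start` and `end − 1`) are screened for pile-ups: positions
with Z > 7 relative to the mean/SD over covered positions are flagged and
the whole fragments touching them are discarded — these pile-ups mark
collapsed repeats and amplification artifacts. Fragments are assigned to
fixed-width bins (300 bp default; 500 bp recommended for human-scale
genomes) by their midpoint: with ~150-bp fragments in 300-bp bins, the
midpoint is the least biased single-bin rule and conserves the library
size exactly. Replicates of the same titration point are pooled as
fragments before normalization; normalization uses the post-filter
retained count.

## GC correction

MNase prefers AT-rich substrates, which leaves a GC-dependent trend in
the slopes. The correction subtracts a LOWESS fit of MACC on per-bin GC
fraction (span 0.3, fitted on a seeded 10,000-bin subsample and linearly
interpolated to all bins), adding the trend's mean back so the stratum
level is preserved exactly. Two numerical choices matter:

- **No robustifying iterations** (default `iterations = 0`). Robust
  LOWESS reweighting treats genuinely accessible/inaccessible bins —
  which carry large |MACC| by biology, not by error — as outliers, biases
  the conditional mean toward the neutral bins and leaves a residual
  GC correlation (~0.07 on simulated data versus ~0.001 without
  reweighting). The iteration count remains configurable for data whose
  outliers really are artifacts.
- **CpG stratification** (mammalian genomes): islands and non-island bins
  are corrected independently, each against its own trend; strata with
  fewer than 100 defined bins are left uncorrected with a warning.

## Segmentation

A two-state Gaussian HMM is fitted genome-wide by EM over the maximal
gap-free runs of defined bins (missing bins break sequences rather than
being imputed, so no transitions are fabricated across unmappable
regions). Ten seeded restarts, tolerance 1e-6, best model by
log-likelihood; the state with the larger emission mean is "accessible".
Decoding uses an in-package log-space Viterbi, verified against
exhaustive path enumeration. The run-length null is the same model class
fitted to the profile shuffled within each chromosome — shuffling
preserves the score distribution but destroys spatial clustering, so
observed-versus-shuffled median run lengths quantify domain organization.

## Peaks, groups, overlap

Peaks are strict local maxima (`value[i−1] < value[i] > value[i+1]`, both
neighbours defined; plateaus yield nothing). Group thresholds are
quantiles of the *positive* score sub-distributions after median
shifting — c-MACC above its positive 80th percentile combined with h-MACC
below its positive 10th percentile (group 1) or above its positive 90th
(group 2) — with strict comparisons throughout, so threshold ties are
excluded. All quantiles use inclusive linear interpolation; partial
terminal bins are excluded from quantile pools. Expected peak/site
overlap is the mean over 10 seeded uniform re-placements of the peaks
onto defined bins (without replacement); the estimator is unbiased for
the site fraction of eligible bins.

## The synthetic titration generator

The simulator provides ground truth for every stage. Expected yield per
bin and point is log-linear in the centred abscissa,

```
λ_ij = b·d + d · exp[(β_i + γ·(GC_i − ½)) · (x_j − x̄)]
```

with depth `d` (default 50 fragments/bin/point; the published fly data
correspond to roughly 60), background fraction `b`, response exponent
`β_i`, and GC-bias strength `γ`. Counts are Poisson; fragment lengths are
Normal(150, 20) truncated to [50, 500] (sub-nucleosomal Normal(110, 15) at
NHP loci); midpoints are uniform within the bin. Because the MACC fit is
the matched estimator of this model, parameter recovery is a clean
calibration surface: `expected_macc` returns the analytic slope implied by
the truth, and regressing fitted on expected slopes yields ≈ 1.0.

Genome layout: accessibility classes are drawn per domain with geometric
domain lengths (mean 20 bins), emulating domain-scale clustering of
chromatin states. Default class fractions are accessible 0.20 (the
accessible state covers about a fifth of a real genome), inaccessible
0.20 and neutral 0.60. The symmetric accessible/inaccessible split
reflects the conservation logic of the assay — material lost to
over-digestion at one end of the titration is the material released at
the other — and gives per-point library sizes that are naturally
comparable, as in real titration sequencing; it also keeps the
genome-wide score median centred, which matters because group thresholds
are defined relative to the shifted median.

Response magnitudes were set by an explicit error budget at depth 50
(slope measurement noise ≈ 0.14 in normalized-frequency units per log
unit): generic accessible/inaccessible bins |β| = N(0.25, 0.05) (≈ 6 SD
from zero — sign recovery is essentially deterministic), neutral bins
β = N(0, 0.15) so that the biological spread is ≈ 3× the measurement
noise, matching the regime of real data where significance weighting
barely changes the scores; NHP and fragile loci draw |β| = N(0.50, 0.05),
the strongest responders, as expected for protein-protected accessible
sites and digestion-sensitive nucleosomes. NHP and fragile flags are
placed (disjointly) on 15% of accessible bins each, ≈ 3% of all bins.

The histone-ChIP pool removes the specific yield of NHP loci entirely and
keeps only the non-specific background `b·d` there (default b = 0.04, i.e.
≈ 8 expected background fragments per bin across four points — minimal
carryover that still keeps 99.97% of NHP bins defined, so their h-MACC is
measurably ≈ 0 rather than missing). The chip-input pool mirrors the
chromatin pool. GC bias enters the response exponent, not the level: a
concentration-independent level bias would cancel in the slope, so only a
concentration-coupled bias can contaminate MACC — at γ = 1 it drives
|r(MACC, GC)| to ≈ 0.55–0.6, which LOWESS correction removes to ≤ 0.01.

What the simulator does *not* emulate: sequence-level cleavage preference
(bias acts at the score level, matching where the correction operates),
count overdispersion beyond Poisson, replicate batch effects, mappability
gaps, and base-pair-resolution nucleosome positioning. Passing tests
therefore demonstrate correctness of the estimators and classifiers under
the stated generative model, not robustness to every artifact of real
libraries.

## Profiles and clustering

Site-centred profiles sample bin-centre values at 1-bp offsets by linear
interpolation (exact on locally linear signal), orient minus-strand
anchors, average across sites, and smooth with a 40-bp centred running
mean truncated (not padded) at the edges, so constants are preserved.
Sample-by-site matrices are clustered by UPGMA on 1 − Pearson r; rows are
sorted by label first, making leaf order deterministic and independent of
input order.

## Problem sizes and defaults

The test and acceptance workloads use 10,000 × 300-bp bins, four
titration points and three pools at depth 50 (≈ 6.6 M fragments per
simulation) — large enough for stable quantile thresholds and HMM fits,
small enough to iterate comfortably on a laptop. Key defaults: bins
300 bp, inserts 50–500 bp, anomaly Z = 7, LOWESS span 0.3 / 0 robust
iterations, group percentiles 80/10/90, quadrant quantiles 80/5/95,
10 overlap randomizations, 40-bp profile smoothing, TSS window ±1 kb
(±2 kb for mammalian annotations), 10 HMM restarts, enrichment
pseudocount 0.5. All randomness flows from explicit integer seeds.

## Known limitations

- Two emission states only; no semi-Markov duration modelling, so very
  long domains are represented by sticky transitions rather than an
  explicit length law.
- P values at k = 4 are coarse; the `(1 − P)` weighting is best treated
  as a sensitivity check, not an error model.
- Group thresholds are distribution-relative (percentiles of positive
  scores); absolute group sizes therefore depend on the score
  distribution and are not comparable across datasets without care.
- The genome-size factor is the only cross-organism normalization; no
  attempt is made to calibrate absolute accessibility between genomes.
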