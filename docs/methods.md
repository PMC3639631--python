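# Methods

## Sequence model and encoding

Sequences are validated DNA strings over {A, C, G, T}. RNA input is
accepted and uracil is folded to T at read time. This is not cosmetic:
the default numeric encoding maps each base to the sum of the atomic
numbers of its nucleobase's atoms (A → 70, C → 58, G → 78, T → 66), and
uracil's sum (C4H4N2O2 = 58) collides with cytosine's, so encoding U as a
fifth symbol would silently corrupt the series. Ambiguity codes (N, R, Y,
…) are rejected by default with the record name and 1-based position; an
opt-in flag drops such records with a logged warning instead. The
rationale for rejecting rather than imputing is that both estimators below
are defined on the 4-letter alphabet and any imputation choice would be
invisible in the output.

The encoding map is a parameter (`EncodingMap`, loadable from a
`base=value` file). The fractal dimension is invariant to affine
re-mappings of the four values — curve lengths scale by |a| under
Int → a·Int + b, which shifts log L(k) uniformly and leaves the fitted
slope unchanged (asserted to 1e-10 in the tests) — so the default map's
particular values matter only if a non-affine alternative is supplied.

## Higuchi fractal dimension

For a series Int(1..N) and lags k = 1..maxK the normalized curve length
is

    L(k) = [ Σ_{i=k+1..N} |Int(i) − Int(i−k)| ] · (1/k²) · (N−1)/(N−k)

— the sum of absolute differences over all index pairs at lag k, with the
first k wrapped differences excluded as end effects, divided by the pair
count (N−k)/(N−1) and by Higuchi's k² calibration factor so that the
maximal attainable dimension of a 1-D signal is the topological value 2.
The dimension is the OLS slope (with intercept) of log L(k) on log(1/k)
over the full integer grid k = 1..maxK. Natural logarithms are used; the
slope is base-invariant as long as both axes share the base. Several
Higuchi variants exist (geometric k-grids, per-offset averaging of
segment lengths); this implementation deliberately uses the single-pass
all-pairs form above, and the test suite pins that exact normalization
against an independent double-loop oracle at 1e-12.

Defaults and contracts:

* `max_k = 7`, exposed everywhere as a parameter. On sequence panels the
  choice is insensitive: nearby cutoffs (6 vs 7) move the dimension by
  < 0.02 on average (asserted on random panels).
* `2 ≤ max_k ≤ N − 1` is enforced.
* Any L(k) = 0 (constant series, strict two-value alternation at even
  lags) raises a hard "degenerate series" error rather than being patched
  with a pseudo-count: the estimator presumes a fluctuating series, and a
  homopolymer's dimension is simply undefined here. Batch drivers record
  the error on the affected row and continue.

Calibration, verified in the acceptance tests: an exact ramp gives
FD = 1 to 1e-10 at every admissible (N, maxK); i.i.d. uniform sequences
of length 10 000 average FD ≈ 2.00 over 50 seeds; fractional Brownian
motion of Hurst H recovers FD = 2 − H within 0.1 at H ∈ {0.2, 0.5, 0.8}.

## Shannon entropies

Mononucleotide entropy −Σ p log₂ p over 4 states (≤ 2 bits) and
dinucleotide entropy over 16 states (≤ 4 bits), computed from plug-in
frequencies with 0·log 0 ≡ 0 and no pseudocounts. Dinucleotides are
overlapping by default (positions (i, i+1), giving N−1 pairs), which is
the standard convention and maximizes counts on short CDSs; `di_step=2`
gives the non-overlapping reading. No bias-corrected estimators
(Miller–Madow, NSB) are offered; at the sequence lengths this package
targets (hundreds to thousands of bases) the plug-in bias is far below
the differences of interest.

## Regression and skewness

Simple OLS of one response on one predictor, reported as slope,
intercept, R² (the squared Pearson correlation) and adjusted
R² = 1 − (1−R²)(n−1)/(n−2) for the single predictor. No p-values: the
pipeline's comparisons are about R² magnitudes and deltas. A constant
response is given R² = 0 by convention (the fitted line explains
nothing); a constant predictor is an error. Skewness defaults to the
adjusted Fisher–Pearson coefficient g₁·√(n(n−1))/(n−2) — the spreadsheet
SKEW convention — with plain g₁ behind a flag.

## Pipeline conventions

* Axis convention is fixed project-wide: x = mRNA FD, y = CDS FD;
  delta = fd_cds − fd_mrna.
* Outliers in FD–entropy maps are excluded only by explicit designation
  (`regress_on`); excluded points are reported with their residual from
  the fitted line. The package refuses to invent a residual threshold.
* Per-record failures (degenerate series, too-short sequences, constant
  expression rows) are recorded on their row and never abort a batch;
  a CLI run exits 2 only when every record failed.
* Reports are deterministic: fixed row ordering, 4-decimal display
  columns plus full-precision companions, byte-identical across runs.
* The concatenated noncoding remainder of a pair requires an unambiguous
  CDS placement (coordinates, or a unique substring match); an ambiguous
  match is an error because picking an occurrence would fabricate UTR
  boundaries. A CDS supplied as a separate record that is not a substring
  of its mRNA keeps the pair but marks noncoding metrics unavailable.

## Synthetic generators

All generators take an explicit integer seed and are reproducible bit
for bit.

**i.i.d. and Markov sequences** provide the null models: uniform i.i.d.
gives FD ≈ 2 and near-maximal entropies; a first-order chain (started
from its stationary distribution) controls dinucleotide structure
independently of composition.

**Fractional Brownian motion** is synthesized by circulant embedding
(Davies–Harte): fractional Gaussian noise with the exact autocovariance
½(|k+1|^2H − 2|k|^2H + |k−1|^2H) is generated spectrally and cumulated.
Negative circulant eigenvalues (tiny rounding artifacts) are clipped at
zero. This gives exact-covariance paths of known dimension 2 − H for
estimator validation.

**The pair panel** plants a linear CDS-vs-mRNA dimension relation
(defaults: slope 1.2, intercept −0.4, scatter sd 0.002, 15 pairs of
which 2 are off-line). Because no closed form links Markov transition
matrices to Higuchi dimensions, targets are hit by bisection on a single
fluctuation parameter θ: θ ≥ 0 repeats the current base with probability
0.25 + 0.75θ (smooth, low FD as θ → 1), θ < 0 prefers a fixed
high-contrast partner base (anti-persistent, FD slightly above 2). The
family's dimension is monotone in θ on [−0.6, 0.95], spanning roughly
FD 1.2–2.1 at the default lengths; each bisection evaluation reuses the
pair's seed so the objective is effectively continuous. The CDS is built
first against its target, then flanking noncoding regions (one shared θ
for the 5' and 3' flanks) are searched so the concatenated mRNA hits its
target. Achieved dimensions must land within a declared tolerance
(default 0.003) of the planted values within a capped iteration budget,
and a target outside the attainable band raises an explicit error.

Design choices inside the panel, made for identifiability:

* The planted mRNA-dimension range (2.025–2.075 by default) lies
  strictly above the point where the planted line crosses the diagonal,
  so every core pair has a positive delta with margin against the
  scatter; the range is wide enough that the slope is well determined at
  13 points given scatter sd 0.002.
* The drawn scatter is orthogonalized against the planted x values
  (mean and covariance projected out, then rescaled to the target sd),
  so the core panel's sample regression line *is* the planted line by
  construction rather than in expectation — recovery error then comes
  only from the planting tolerance, a fraction of a percent on the
  slope, for any seed.
* The two off-line pairs are placed in the lower interior of the range
  with their CDS dimension displaced 0.02 below the line. Interior
  placement keeps their leverage modest, so including them always lowers
  the panel R² (placing them outside the range can *raise* R² through
  the leverage of an extended x-range — the opposite of the structure
  being planted).

**The expression table** emulates brain-wide expression z-scores: 168
regions × 4 donors per gene, each gene drawn from a distribution of
planted skewness — standard normal for skew 0, standardized lognormal
otherwise, with the lognormal shape parameter solved from the target
skewness by root finding (negated for negative targets). Rows are
standardized to mean 0, sd 1 (affine, so skewness is untouched). The
default four-gene panel plants skews 2.2, 1.1, 0.91 and 0.04 — a
hormone pair with a ~2× skewness ratio and a receptor pair whose ratio
is large but fragile (see limitations).

What the generators do **not** emulate: codon structure, splice signals,
GC-content gradients along real UTRs, inter-gene correlation of
expression, or donor effects. Passing the recovery tests therefore shows
that the estimators and pipeline logic are correct and well calibrated
on sequences with controlled fractal/entropy structure — not that real
transcripts follow the planted relation.

## Problem sizes

Stochastic calibrations use series of length 10 000 (50 seeds for the
i.i.d. null, 20 per Hurst value for fBm); the planted panel uses 15
pairs with 1200-base CDSs and mRNAs of roughly 1.8–3.4 kb; entropy
bound checks sample 1000 random sequences up to 5 kb; skewness checks
use the full 672-sample atlas-scale rows. The complete test suite runs
in well under a minute on one CPU, the acceptance script in seconds.

## Known limitations

* Sample skewness of heavy-tailed distributions is biased low at
  n = 672 (the planted 2.2-skew gene typically measures ≈ 1.7–2.2), so
  planted and measured skews agree in ranking, not in value.
* The receptor skewness *ratio* divides by a value whose planted
  magnitude (0.04) is smaller than the sampling noise of skewness at
  n = 672 (≈ 0.09), so its sign and magnitude vary wildly across seeds.
  The package reports it, but the stable summary is the ranking and the
  hormone-pair ratio.
* Multi-exon / noncontiguous CDSs are out of scope: CDS placement is a
  single contiguous block.
* The Higuchi estimator is reported for the specific normalization
  documented above; other normalization families give systematically
  offset dimensions and should not be compared numerically without
  recalibration.
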