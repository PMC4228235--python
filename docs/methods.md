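# Methods

This note records the statistical procedures, conventions and numerical
choices behind `devchar`, and what the synthetic-data experiments do and do
not establish.

## Data model

Expression values are log2-scale normalized intensities (the output of an
upstream RMA-style normalization, which is out of scope here) in a features
× samples matrix. Sample ages live on one monotone axis in days: prenatal
ages as days post conception, postnatal ages offset by gestation length
(supplied in metadata; the default murine grid uses 19.5 days). Features
with any missing value are dropped on read with a logged count; any other
non-numeric cell is a hard parse error naming the row and column. Written
matrices use full repr precision and round-trip bit-exactly (the reader
re-parses with correctly-rounded float conversion).

## Probe-to-gene collapse

Two collapse rules, one per study design:

* **Replicate-correlation collapse** (time series): per probe, the Pearson
  correlation between the two replicate profiles ordered by age; per gene,
  the maximum-correlation probe represents it. Probes with a zero-variance
  profile get an undefined (NaN) correlation and lose to any defined one.
* **Minimum-p collapse** (paired cohorts): the probe with the smallest
  signed-rank p represents the gene.

Ties in either rule break to the lexicographically smallest probe id — a
measure-zero event on real data, pinned for platform-independent
determinism. Probes absent from the map are excluded with a logged count.

## Standardization and PCA

Columns (samples) are standardized to mean 0, variance 1 across genes,
using the sample-variance denominator (n − 1). All columns have the same
length, so the denominator choice rescales every column identically and
cannot change component directions; it is documented only so results are
exactly reproducible. Zero-variance columns are an error naming the sample.

Before decomposition each gene's values are centered across samples, so
components describe the variation of the sample cloud about its centroid
(an uncentered decomposition is available behind `center_genes=False` for
sensitivity analysis). The decomposition is a singular value decomposition
of the centered matrix; gene loadings are the left singular vectors (unit
norm, mutually orthogonal), sample scores the scaled right singular
vectors, and explained-variance fractions the squared singular values over
their total. Component signs are fixed so each loading vector's
largest-magnitude entry is positive; all downstream quantities use loading
magnitudes and are sign-invariant.

Within each component genes are ranked by decreasing |loading| (rank 1 =
largest; ties break by gene id). The per-component characteristic set is
the top round(0.05·N) genes (half-up rounding; the fraction is
configurable), and the dataset-level characteristic set is the union over
PC1–3. The rule is applied at collapsed-gene level by default; running it
at probe level is a caller choice.

## Local regression smoothing

An optional per-feature smoother for noisy or irregularly aged series:
locally weighted polynomial regression with tricube weights over the
span-nearest neighbours (k = ⌈span·n⌉), evaluated at the observed ages.
Defaults: span 0.7, local linear (degree 1). The fit reproduces
polynomials up to its degree exactly; spans too small to cover degree + 2
points are rejected. The smoother is provided generically and is not wired
into the default pipeline, since which dataset class benefits from it
depends on the age-estimation noise of the study at hand.

## Paired differential expression

Per feature, within-pair differences d_i = A_i − B_i feed the Wilcoxon
signed-rank test; W is the sum of ranks of positive differences after
midranking |d|. Conventions, all echoed into output metadata:

* zero differences are discarded before ranking (Wilcoxon's convention);
  `zero_method="keep"` retains them Pratt-style, in both the ranking and
  the null moments;
* exact p (two-sided, by doubling the smaller tail of the convolution-built
  null distribution of W) when n ≤ 25 and |d| is tie-free; otherwise the
  normal approximation with tie-corrected variance and a 0.5 continuity
  correction;
* significance is strict raw p < α (default 0.05); no multiplicity
  adjustment enters the significant set, matching the raw-p overlap design
  this pipeline serves, but a Benjamini–Hochberg column is emitted for
  context.

The log2 fold change is the arithmetic mean over condition A minus the mean
over condition B (both already log2), so it is antisymmetric under label
swap.

## Over-representation inference

For sets A and B in universe U (an explicit argument — all genes measured
on the platform after collapse; set members outside U are dropped with a
logged count), the 2×2 table fixes all margins, and cell *a* follows the
noncentral hypergeometric distribution with odds ratio ψ. One log-space
kernel (log-binomial weights, log-sum-exp normalization) backs every
statistic:

* **Fisher two-sided p** by the point-probability rule — the total
  probability of tables no more probable than the observed one, with the
  customary 1 + 1e−7 relative slack on the comparison (the convention of R
  and scipy);
* **cross-product OR** ad/bc (flagged infinite/undefined on zero cells) and
  the **conditional MLE**, the root of E_ψ[X] = a, found by Brent's method
  on log ψ to relative tolerance 1e−8 (0/∞ at the support boundaries);
* **exact tail-inversion CI**: ψ_L solves P(X ≥ a | ψ) = α/2, ψ_U solves
  P(X ≤ a | ψ) = α/2;
* **Cornfield CI** (reporting default): solves
  (a − E_ψ[X] ∓ ½)² = z²_{α/2}·Var_ψ[X] on either side of the CMLE, i.e. a
  chi-square inversion of the conditional moments with continuity
  correction.

Both intervals are always computed and reported side by side. The Cornfield
interval is the default *printed* interval because it is the convention of
classic epidemiological software and reproduces the published
contingency-analysis intervals this pipeline is designed to re-derive; the
exact interval is the strictly conservative choice and matches
`fisher.test`. Both bracket the CMLE. The cross-product OR is the default
point estimate, with the CMLE always alongside.

## Synthetic data

The generators emulate the two study designs at their published scale and
are the fixture factory for every test:

* **Developmental series** (defaults: 2,000 genes, the 15-point murine age
  grid E9.5→P56 on the day axis, biological duplicates, 5% planted genes,
  program amplitude 1.5 and noise 0.5 log2 units — a 3:1 ratio
  representing a strong developmental program against typical array
  noise). Planted genes follow one of three program families — monotone
  logistic ramps, stage-switch steps, transient pulses — anchored at a
  canonical mid-developmental epoch with modest gene-to-gene jitter,
  because coordinated stage transitions are what make a planted minority
  drive the *dominant* sample-variation axes; 75% of programs increase
  with age, emulating the predominance of late-development induction.
  Programs are shared across replicates; noise is independent.
* **Paired cohort** (defaults: 2,000 genes, 95 pairs, 5% planted with a
  1.0 log2 shift in condition A, noise 0.4, pair-shared baseline 0.5 log2
  units inducing the within-pair correlation a paired test exploits).
* **Probe expansion**: each gene gets 1..k probes (gene row + independent
  noise), one designated low-noise representative per gene, so both
  collapse rules have a well-defined target.

All generators are pure functions of their config including the seed.
Gaussian log2-scale noise is the conventional log-normal-intensity
assumption; the generators do not emulate probe-sequence effects, batch
structure, normalization artifacts, or correlated gene modules beyond the
planted programs. Consequently, passing recovery tests show the pipeline's
operations are correct and calibrated under the stated model — not that
characteristic-gene lists from real arrays are free of platform artifacts.

## Problem sizes in the test suite

The suite verifies Fisher p against direct enumeration exhaustively for
every table with total ≤ 60 and on a seeded sample of 500 tables with
totals up to 200 (agreement to 1e−12); exact-CI tail masses by direct
summation to 1e−6; Wilcoxon exact p against full 2ⁿ sign-flip enumeration
for all n ≤ 12; null calibration on 50 seeded cohorts of 2,000 features ×
95 pairs; and planted-gene recovery on 20 seeded series at the default
configuration. These sizes keep the full suite to a few minutes while
leaving each check statistically decisive.

## Known limitations

* The exact Wilcoxon path requires tie-free magnitudes; midrank ties at
  n ≤ 25 fall back to the approximation rather than a tie-aware exact
  enumeration.
* Cornfield bounds are approximate by construction; for very sparse tables
  the exact interval should be preferred (both are always reported).
* The replicate-correlation collapse is defined for exactly two replicate
  series, the design it was conceived for; more general designs need a
  different reproducibility score.
* The PCA stage assumes a complete matrix; features with missing values
  are dropped, not imputed.
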