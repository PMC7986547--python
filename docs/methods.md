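# Methods

## The measurement model

A TRF lane is summarised by its intensity profile: for scan row k (0-based
here; 1-based in user-facing files), OD_k is the sum of pixel optical
densities across the lane's selected columns.  Hybridisation signal is
proportional to telomeric *mass*, so a row at fragment length L_k with
intensity OD_k represents a fragment count proportional to OD_k / L_k.  All
length statistics are therefore quantiles of the count-weighted
distribution: the cumulative curve

    C_k = sum_{m<=k} OD_m / L_m

is inverted by linear interpolation between the bracketing pair
(C_i, L_i), (C_{i+1}, L_{i+1}) at C_n/2 for the median and at C_n/4 and
3C_n/4 for the quartiles.  When the target falls below C_1, the curve is
extended continuously to (0, L_0) with L_0 the linear row-space
extrapolation one row before the segment (2L_1 − L_2); the quartile
construction as quarter-points of C is one concrete reading of
"quartiles based on the weighted median" — the median machinery applied at
the quarter targets.  Minimum and maximum are the calibrated lengths at the
two border rows of the selection.  Profiles are smoothed before evaluation
(see below); lengths never are.

## Parameters that matter

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `W` | 0.28 | border-threshold width constant; the left threshold is OD_lb + W·(OD_lmax − OD_lb), mirrored on the right. 0 opens the selection to the flanking baseline, 1 collapses it onto the peak. |
| `span` | 0.05 | smoothing span: centered moving average with window max(3, round(span·n)), forced odd, edges shrink. Applied before border search and before evaluation. |
| `alpha` | 0.05 | significance of each nested-model F-test in polynomial order selection. |
| `sensitivity` | 0.1 | ladder peak search: required prominence as a fraction of the smoothed profile's range. Peak search uses a 1% smoothing span — the 5% evaluation span merges adjacent ladder bands. |
| `max_order` | 6 | polynomial order ceiling, additionally capped at (#bands − 2) so a residual degree of freedom remains for the last F-test. |

## Calibration

Fragment length is regressed on pixel row (raw bp, not log bp; the
data-driven polynomial order absorbs the curvature of the log-like
migration law).  Orders ascend 1 → 2 → … while each nested F-test rejects
at p ≤ alpha; the first non-rejection stops the ascent and the deepest
consecutively-rejected order is kept.  Exact fits (RSS numerically zero)
are treated as rejections when the simpler model has residual, and as
non-rejections when both models interpolate.  Polynomials are fitted in a
scaled domain (`numpy.polynomial.Polynomial.fit`) for conditioning;
coefficients are reported in raw powers.

Tilt ("smiling" in its straight-lane form) is corrected with virtual
markers: for every fragment length shared by the two flanking ladders, the
band row is linear in the column coordinate through the two ladder
positions, evaluated (or extrapolated) at each lane's center column.  Each
virtual ladder is fitted as above; the most frequent selected order is
imposed on all lanes (ties resolved toward the smaller order, for
parsimony), so all lanes share one model class.

A non-monotone ladder assignment (rows not increasing as length decreases)
is a warning, not an error: partial or unusual assignments are legitimate.
Predicted lengths below 1 bp are floored at 1 with a warning; they occur
only on extrapolation far outside the fitted band range.

## Smear selection and background

Border rows are the *outermost* rows at which the smoothed profile crosses
its threshold, scanning inward from the profile ends — the widest area
consistent with the threshold.  The flat-profile case (no max–baseline
contrast on either side) raises "no telomere-specific signal".  If W ≈ 1
collapses both crossings onto the peak row, the minimal 3-row selection
around the peak is returned.

Background is a straight line through two anchors, one per flank of the
selection.  In each flank interval, local minima of the *smoothed* profile
(strict first-difference sign changes; plateaus contribute their center
row) are kept when below the interval's median; with ≥ 3 of them a line is
fitted through the *raw* OD at those rows and the anchor is that line's
value at the midpoint of the minima's row range, otherwise the interval
minimum is the anchor.  Raw (not smoothed) OD values are used for the
anchors because the shrinking smoothing window biases edge values on a
sloped baseline by about span/2 of the slope — enough to leave a ~1%
residual on a pure ramp, which the raw-value anchors remove exactly.  The
corrected profile is clamped at zero.  Correction is refused for manually
drawn borders, where nothing guarantees the flanks are signal-free.

The canonical per-lane path (`analyze_profile`, also what the CLI runs)
re-runs the automatic border selection on the corrected profile before
evaluating: a strong baseline can push the raw-profile threshold crossings
far beyond the smear, and re-selection restores the selection the clean
signal would have produced.  Without correction, a rising baseline biases
the estimate *downward* — background at the short-fragment end is amplified
by the 1/L weighting — which is the practical reason the correction exists.

## Group statistics

Each lane contributes (weighted median, q1, q3, n) with n the pixel count
of the selected smear.  Mean and SD are recovered with the median+IQR
formulas of Wan et al.:

    mean ≈ (q1 + median + q3) / 3
    SD   ≈ (q3 − q1) / (2 Φ⁻¹((0.75 n − 0.125)/(n + 0.25)))

Lanes sharing a group label are pooled with the Cochrane two-sample
combination applied as a left fold; the result equals the moments of the
concatenated raw data exactly (verified against a concatenation oracle), so
pooling is order-independent.  Hypothesis tests run on *mock data*: per
group, n_lanes normal draws re-standardised so the sample mean and SD
(ddof = 1) equal the pooled moments to machine precision.  Test outcomes
therefore depend only on (mean, SD, number of lanes) and the seed, which is
what makes analyses reproducible from the report file alone.

Welch's t-test (two-tailed, Welch–Satterthwaite df) is the base comparison;
multiple Welch (unadjusted) is the recommended default since type II error
is the more plausible risk at 3–5 lanes per group.  Tamhane–Dunnett is
realised as Sidak-adjusted Welch comparisons against the control (T2
family); Games–Howell refers |t|·√2 to the studentized range with k groups
and the pair's Welch df.  Degenerate zero-variance pairs use the p = 1 /
p = 0 convention for equal / unequal means.  Groups need ≥ 3 lanes.

## Synthetic gels and what they do (not) show

The generator builds gels from a monotone migration law row = a − b·ln L
(defaults a = 820, b = 85 on a 420-row gel, placing 10 kb at row 37 and
1 kb at row 233), ladder bands as row-space Gaussians, and smears whose
intensity density over bp is lognormal or a mixture of narrow bands.  Pixel
signal is the bp density carried through the migration Jacobian, so the
analytic 1/L-weighted quantiles of the recipe's density are the exact
ground truth for the estimator.  Composition order: signal + background
gradient + blotches, truth captured, then noise, then clipping; a lane with
> 20% saturated pixels triggers a dynamic-range warning.

Default study conditions emulate wild-type *Arabidopsis thaliana*-like
telomeres: lognormal smear with median 3 kb and log-sd 0.15 (smear roughly
2.2–4.1 kb), between-lane jitter of 0.05 on the log median (~150 bp),
pixel noise sd 0.01, background up to ~30% of the signal peak.  Under these
conditions a true 30% group difference with 5 lanes/group is detected
(p < 0.1, Welch on mock data) in well over 80% of replicates.  Real
membranes add what the generator does not model: curved ("smiling") lanes
beyond a linear tilt, spatially correlated exposure noise, saturation
nonlinearity, and inter-individual spread that can exceed the default
jitter — so passing these checks demonstrates correctness of the
algorithms, not field performance on any particular membrane.

## Numerical choices and edge cases

- Grayscale reduction uses BT.709 luminance weights; integer rasters are
  scaled by their dtype maximum.  Signal is bright by convention; use
  `--invert` for dark-band scans.
- Multi-rectangle markers merge by per-row *mean*, so ladders drawn from 2
  or 3 adjacent lanes have comparable magnitude.
- Profile extraction is exact row summation (linear; column-splits add).
- Workbook round-trips are lossless to float precision; third-party
  workbooks without a metadata sheet import as role `sample` with unknown
  selection.
- The noisy-ladder order-selection check uses homoscedastic noise at 0.5%
  of the mean band size; proportional (heteroscedastic) noise inflates the
  F-test's rejection rate and is not what the chain's alpha calibrates.
- Problem sizes in the acceptance script (420-row lanes, 20 gels, 100
  detection replicates, 5,000–10,000 test replicates) are chosen so the
  whole run completes in a couple of minutes on one CPU while keeping
  binomial noise well inside the asserted margins.

## Known limitations

- No automatic lane finding and no rectification of curved lanes; curved
  audiograms should be profiled in third-party software and imported as a
  workbook.
- Background correction is 1-D (per profile); 2-D artifacts inside the
  smear must be avoided by narrowing the lane selection instead.
- The Tamhane–Dunnett variant is T2-style (Sidak-adjusted Welch); T3
  (studentized-maximum-modulus) critical values would differ slightly.
- Quartile recovery assumes approximate normality inside each lane's smear
  (inherent to the Wan formulas); strongly multimodal lanes stretch that
  assumption, which is why the violin display exists.
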