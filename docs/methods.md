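# Methods

## Statistical model

Each patellar measurement (MAXH, MAXT, MAXW, in mm) is modelled per sex as a
univariate normal distribution with the sample mean and sample SD
(divisor n − 1). Two classifiers are built on top of this model.

**Sectioning point.** The cut-off x₀ between predicted females (below) and
males (at or above) is the point where the two fitted densities are equal.
Equating log-densities gives a quadratic in x for unequal SDs (a single
midpoint solution for equal SDs); the admissible root is the one strictly
between the two group means. The D-value

    D = F(x₀ | x̄_f, s_f²) − F(x₀ | x̄_m, s_m²)

is the area of non-overlap of the two distributions and the package's figure
of merit for dimorphism; dD/dx₀ = φ_f(x₀) − φ_m(x₀), so D is maximised
exactly at an in-interval density crossing. When the SDs are sufficiently
unequal, both quadratic roots can fall outside the interval between the
means (this happens for the embedded burnt-thickness summaries); the
implementation then takes the D-maximising point on the closed interval
between the means — which by the derivative argument is an endpoint — and
flags the result (`fallback=True`). If the female mean exceeds the male mean
the groups are swapped internally and the result flags reversed polarity.

Tie-break: a value exactly at x₀ classifies as male, because the female rule
is strictly "falls below the cut-off".

**Linear discriminant.** For measurement vector x the score is
Y = wᵀx + c with w ∝ S_p⁻¹(μ_m − μ_f), S_p the pooled within-group
covariance (divisor n − 2). The scaling convention is the one classical
anthropometric software reports as "unstandardized coefficients": w is
rescaled so the pooled within-group variance of the training scores is 1,
and c = −wᵀx̄ (case-weighted grand mean) so the n-weighted per-sex centroids
sum to zero. This convention is verifiable against the published combined
function: its centroids (−0.569, 0.732) satisfy 18·(−0.569) + 14·0.732 ≈ 0,
and applying its printed coefficients to the per-sex mean vectors of the
burnt sample reproduces the centroids to within table rounding
(−0.550 / 0.753 vs −0.569 / 0.732). Classification uses equal priors
(threshold at the centroid midpoint, boundary to female — fixed and
documented so the two classifiers' tie-breaks are explicit). Leave-one-out
cross-validation refits the full model for every held-out case; no shortcut
update formulas are used, accepting O(n) refits for transparency at study
sizes (n = 32).

**Hypothesis tests.** Shapiro–Wilk is applied per sex group per measurement
(the per-group reading is the one that makes a subsequent Levene comparison
meaningful); Levene is mean-centred; both delegate to scipy. The
Mann–Whitney U test is implemented directly because its reporting convention
is pinned: midranks for ties, z = (U_f − n_f n_m/2)/σ_U with tie-corrected
σ_U and **no** continuity correction, two-sided normal p, and z negative
when the female group tends lower. An exact-enumeration mode (all
C(n, n_f) group assignments; feasible for groups ≤ 10) is provided as a
cross-check. Significance is interpreted in the standard way (p < α).
Skewness is the adjusted Fisher–Pearson G1, the common statistics-package
default.

**Observer error.** For n subjects each measured twice,
TEM = √(Σd²/2n) (mm), %TEM = 100·TEM/grand mean, and R = 1 − TEM²/s² with
s² the sample variance (divisor n − 1) of the per-subject means. The TEM
literature admits variants of s²; per-subject means are used here and fixed.
Exactly two replicates are supported — the intra-/inter-observer design —
keeping the formulas unambiguous. %TEM's denominator is the grand mean of
the measurement being analysed (each measurement is analysed separately
throughout).

## Synthetic data generator

The generator emulates the study design: n_f = 18 female and n_m = 14 male
individuals, each with a left unburnt patella drawn from a sex-specific
trivariate normal and a right burnt antimere derived from it. Defaults:

- **Means/SDs**: the embedded unburnt per-sex summaries (e.g. female MAXH
  37.95 ± 2.98 mm, male 42.45 ± 2.23 mm).
- **Inter-measurement correlation**: 0.6 between all pairs. Patellar
  dimensions are strongly but not perfectly correlated; no correlations are
  published for this sample, so the value is a single configurable choice.
- **Heat shrinkage**: one multiplicative factor per individual applied to
  all three dimensions, s ~ N(mean, 0.02²) truncated to [0, 0.5], with mean
  0.08 for females and 0.11 for males. These magnitudes are placeholders —
  the source sample's shrinkage was reported only qualitatively (higher in
  males) — and must not be read as estimates of it.
- **Missingness**: with probability 24/56 all three burnt values are absent
  (the reported fraction of burnt patellae rendered unmeasurable), jointly
  rather than per-dimension, since heat damage that defeats one calliper
  measurement usually defeats the others.
- **Burn metadata**: temperature uniform on {450,…,1100} °C, duration
  uniform on [90, 240] min (the reported experimental ranges); colour is
  white at ≥ 800 °C and black below, tying the calcined filter
  deterministically to temperature. Real calcination also depends on
  duration and oxygen, which are ignored.
- **Ages**: uniform integers in the reported per-sex ranges (females 62–92,
  males 60–93); ages feed no downstream computation.

What the generator does **not** emulate: measurement error, left–right
asymmetry beyond shrinkage, age effects on bone size, non-normal tails,
correlation between shrinkage and burn temperature, and per-dimension
shrinkage differences (trabecular-rich thickness shrinks more in real bone).
Passing tests on synthetic data therefore validate the statistical machinery
under the stated model, not the field behaviour of the method on real
cremated remains.

Determinism: one `numpy` Generator seeded from the config drives all draws
in a fixed per-individual order, so a seed fixes the dataset bit-for-bit.

## Numerical choices

- Quadratic root selection as above; candidates are the in-interval roots
  plus the interval endpoints, scored by D-value.
- The sectioning-point test oracle is a two-stage grid scan of D on the
  interval between the means (coarse step 10⁻³ mm, fine step 10⁻⁶ mm around
  the coarse optimum); closed form and oracle agree to 10⁻⁴ mm over 1,000
  random summary pairs.
- Degenerate inputs: zero group SD, equal means, constant groups, empty
  sexes and singular pooled covariances are hard errors with named messages;
  a singular leave-one-out fold is excluded with a warning rather than
  aborting the whole cross-validation.
- Percentages are case-weighted: the total accuracy is correct cases over
  all cases, not the mean of the per-sex rates.
- Report rounding: 2 decimals for mm, 3 for D-values and p-values, 1 for
  percentages; full precision is kept in `results.json`.

## Reference fixtures and their quirks

The embedded per-sex summary tables for the burnt sample and its unburnt
antimeres are transcribed verbatim from the published tables. Some printed
cells are internally inconsistent (a male burnt-height maximum below its
mean; several unburnt min/max cells incompatible with their means); they are
stored as printed, feed no computation, and the summary type checks ordering
via a `consistent` property instead of enforcing it. The published unburnt
thickness and width cut-offs (19.41, 41.28 mm) reproduce exactly from the
printed summaries under the density-intersection definition; the published
unburnt height cut-off (40.20) and the burnt cut-offs do not (they are
consistent with unrounded raw data we do not have), so validation anchors on
what is reproducible: the burnt D-values evaluated at the published
cut-offs (0.423 / 0.220 / 0.453) and the two unburnt cut-offs above.

## Validation problem sizes

The test suite uses 5,000 cases per sex for the discriminant
direction-recovery check (fitted direction within 5° of the population
Fisher direction), 500 study-sized replicates (18/14) for the
cross-validated accuracy band (mean total accuracy required in [60%, 85%];
observed ≈ 72–73%, bracketing the published 68.8–75% range), 1,000 random
summary pairs for the sectioning oracle, and 500 subjects for the TEM
error-recovery check.

## Known limitations

- Strictly two groups and two-normal sectioning; no kernel-density or
  quadratic-discriminant variants, no stepwise selection.
- Published per-individual data are unavailable, so the printed
  classification percentages and TEM ranges are not recomputable; they are
  bracketed stochastically (accuracy band) or replaced by hand-verifiable
  micro-examples (TEM).
- The reliability module supports exactly two replicates per subject.
- The elderly, single-population study design limits any claim of
  generality; the package reproduces and stress-tests the method, it does
  not extend its population validity.
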