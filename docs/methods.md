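# Methods

This note documents the models, conventions and numerical choices behind
`bluecarb`, and what the synthetic-data tests do and do not demonstrate
about real sediment-core compilations.

## The CF:CS chronology model

The constant flux–constant sedimentation model assumes (i) a constant
atmospheric supply of unsupported ("excess") ²¹⁰Pb to the sediment
surface, (ii) a constant mass accumulation rate MAR, and (iii) no
post-depositional mobility or mixing. Excess activity then decays with
cumulative dry mass *m* (g cm⁻²):

    A_xs(m) = A_xs(0) · exp(−λ m / MAR),      λ = ln 2 / 22.3 yr⁻¹.

`fit_cfcs` regresses ln A_xs on *m* by ordinary least squares and reports
MAR = λ/|slope|, SAR = MAR/ρ̄, and slice ages *m*/MAR. Choices a user
should know about:

- **Coordinate.** The regression runs on cumulative mass by default
  because the model is defined on mass flux; `coordinate="depth"`
  regresses on midpoint depth (slope −λ/SAR) for sensitivity analysis.
  On a uniform-density core the two are identical.
- **Mean density ρ̄** is the dry-mass-weighted mean dry bulk density of
  the slices used in the fit, so SAR and MAR always refer to the same
  sediment interval.
- **Supported ²¹⁰Pb.** When every slice carries a supported-activity
  measurement (e.g. ²²⁶Ra), their mean is subtracted; otherwise the mean
  total activity of the three deepest slices (the "deep plateau") is
  used and a warning flag is raised if that level exceeds the smallest
  total activity in the upper half of the profile.
- **Non-positive excess** slices are excluded from the fit — never
  clamped, which would bias the log-linear fit — but still receive ages
  by model extrapolation.
- **Weighting** is unweighted by default (the common CF:CS practice);
  inverse-relative-variance weighting from the activity errors is
  available (`weighted=True`).
- At least 3 positive-excess slices are required; a non-negative slope
  is reported as "no decay trend" rather than silently producing an
  infinite rate.

**Known bias.** When a core barely reaches radiometric equilibrium, the
deep-plateau estimate of supported activity absorbs some genuine excess,
which steepens the fitted slope and biases SAR low (≈15–20 % on the
default synthetic profiles). This is a property of the estimator on
under-long cores, not of the implementation: subtracting the true (or
measured) supported level recovers the true SAR to well under 5 % in the
median under 10 % activity noise.

## Carbonate accounting

C<sub>inorg</sub> concentration is ρ̄ · (%CaCO₃/100) · f_C with
f_C = 0.12 — the accounting convention of a flat 12 % carbon mass
fraction in CaCO₃; the molar-exact 12.011/100.087 ≈ 0.1200 is available
through the configuration. Both %CaCO₃ and ρ̄ are averaged over the same
post-1900 window (slice-midpoint convention), so concentration and
burial refer to one body of sediment. Burial is SAR × concentration ×
10⁴ (gC m⁻² yr⁻¹); zero-carbonate cores yield zero and stay in the
dataset. Undated cores produce concentration and %DW statistics only.
The CaCO₃ vertical-accretion conversion divides by an *effective
density* supplied by the caller (bulk sediment density for a
share-of-elevation reading, 2.71 g cm⁻³ for a compact-mineral
equivalent); no default claim is made about which one applies.

## Aggregation and upscaling

Cores from the same site/area with the same allochthonous-source state
are replicates of one *location*; metrics are averaged per location
(SE from two cores up) before any global statistic, so densely-cored
sites do not dominate. Location-level distributions are strongly
bimodal — source-adjacent locations cluster near 60 %DW CaCO₃,
source-free ones below 10 %DW — so the median (IQR) is the headline
central tendency, with mean ± SE always reported alongside. Quantiles
interpolate linearly between order statistics (the convention where the
p-th quantile sits at fractional index p·(n−1)); IQR values depend on
this choice. The normality screen is Shapiro–Wilk at α = 0.05, advisory
only: it never gates a computation.

Global burial is rate × area × 10⁻⁶ (gC m⁻² yr⁻¹ × km² → Tg yr⁻¹), with
a two-significant-figure presentation helper; the zone-partitioned
variant assigns 2/3 of the seagrass area to the tropical/subtropical
zone by default and reproduces the unpartitioned estimate exactly when
the zone rates are equal.

## CO₂ budget

ψ = 0.6 mol CO₂ per mol CaCO₃ is a fixed scalar; no carbonate-chemistry
dependence (temperature, salinity, pCO₂) is modelled. Sign conventions:
negative net calcification (net dissolution) produces negative emission
— a CO₂ sink — and is propagated, never clamped; the allochthonous
fraction 1 − max(calcification, 0)/burial is clamped to [0, 1], with a
flag when local production exceeds burial. Range arithmetic pairs bounds
index-wise (low emission over low C<sub>org</sub> burial, high over
high). Rounding for presentation never feeds back into stored values.

## Effect statistics

Hedges' g, its correction factor J = 1 − 3/(4(n_E+n_C−2)−1), pooled SD
and variance V_g are implemented directly from the standard formulas and
are cross-checked in the test suite against an independent brute-force
evaluation and, for the DerSimonian–Laird pooling, against statsmodels.
The DL between-study variance is the truncated moment estimator
(τ² ≥ 0). Pooling is deliberately one-level: a multilevel variance
structure (study/province random terms) would require modelling
decisions the available summary data cannot constrain, so the package
reports the well-defined single-level estimator instead and treats
multilevel results as approximate context.

Studies in the paired vegetated/unvegetated contrast need n ≥ 2 in both
habitats (a single core has no SD); single-core groups are representable
in `GroupStats` but are excluded from pooling, and the returned k counts
survivors.

The Mann–Whitney U test (statistic of the first sample, two-sided by
default) uses exact enumeration for tie-free samples with n_a+n_b ≤ 12
and the tie- and continuity-corrected normal approximation otherwise.
For 3 ≤ n_a, n_b ≤ 6 the one-sided normal approximation is within 0.02
of exact enumeration for *every* achievable U (verified exhaustively in
the tests); two-sided p-values of such tiny samples are step functions
with jumps of 0.1 and larger, which no continuous approximation can
track — use the exact method there, as the default does.

## The synthetic-core generator

`generate_core` emulates what the analysis assumes: an exactly
exponential excess-²¹⁰Pb profile over a supported plateau, multiplied by
lognormal noise of a given CV (mean exactly 1; counting errors scale
with activity — additive Gaussian noise is available behind a flag), and
CaCO₃ %DW drawn from a logit-normal regime conditioned on
allochthonous-source presence (logit mean 0.41 ≈ 60 %DW with sources,
−3.5 ≈ 3 %DW without), reproducing the bimodality of real compilations.
Defaults: SAR 0.22 cm yr⁻¹, DBD 1.0 g cm⁻³, surface excess 300 Bq kg⁻¹,
supported 20 Bq kg⁻¹, noise CV 0.1, and 20 × 2 cm slices — deep enough
to reach the supported plateau, as real cores sampled to radiometric
equilibrium are. `measure_supported=True` additionally records per-slice
supported activities (²²⁶Ra-style, same relative noise), enabling the
"given" supported method end to end. All generators are pure functions
of (scenario, seed) using numpy's seeded Generator; no global state.

What passing tests on this generator show: the estimators invert the
model they assume, exactly in the noiseless limit and with calibrated
error under noise, and the aggregation/upscaling arithmetic is correct.
What they cannot show: robustness to violations the generator does not
produce — bioturbation and sediment mixing, compaction, non-constant
²¹⁰Pb flux or sedimentation, depth-correlated CaCO₃, or spatial
correlation between locations. Conclusions about real cores inherit the
CF:CS assumptions.

## Problem sizes

The test suite uses desk-scale Monte-Carlo sizes chosen to make the
statistical assertions stable: 200 replicate cores for SAR recovery,
1,000 replicates for the type-I error of the pooled test, 100 replicate
datasets (7 paired locations each) for the null vegetated/unvegetated
contrast, 400 replicates for the normality-screen acceptance rate, and
exhaustive enumeration (all U values, all size pairs 3–6) for the
Mann–Whitney comparison. The acceptance script's quantities are
deterministic arithmetic on the documented global inputs.

## Known limitations

- No CRS (constant rate of supply) or CIC chronology models; cores whose
  ²¹⁰Pb flux varied in time will be mis-dated by CF:CS.
- The mass-depth coordinate ignores unsampled gaps between slices (they
  contribute no mass).
- Area uncertainty enters only as a low/high extent range; no
  distributional treatment of habitat area.
- The budget module treats ψ as universal; in reality the released-CO₂
  ratio varies with the carbonate system state of the water.
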