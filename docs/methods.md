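# Methods

This note documents the models, estimators, numerical choices and known
limitations of `droughtgen`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Ring-width data

Increment cores are read from Tucson/rwl text (decadal rows, 8-character
series id) or long-form CSV. The two unit dialects are distinguished by the
end-of-series terminator: `999` means values in 0.01 mm, `-9999` values in
0.001 mm; an explicit dialect overrides detection. Zero values are retained
as 0.0 mm widths (a locally absent ring is biologically meaningful) and
downstream ratio operations guard against them; years a core does not cover
are missing. Cores of the same tree are averaged per year over whichever
cores have a measurement that year — two cores is the usual design, but any
number is accepted.

Site chronologies (used to visualise common signal, not for the genetic
analyses) divide each tree by a fitted deterministic trend — modified
negative exponential `a·exp(−bt) + k` with `a, b > 0, k ≥ 0`, falling back
to a straight line, falling back to the series mean — and average the
dimensionless indices per year, by default with a one-step Tukey biweight
robust mean (c = 9, median/MAD scaled). Detrending method and averaging are
recorded in the chronology object. With series-mean detrending every tree's
index averages to 1 over its span, a property the tests exercise.

## Site precipitation and the SPI

Monthly station precipitation is interpolated to the site by
inverse-distance weighting with weights `d^(−power)` (default power 2) on
haversine great-circle distances; a station within ~1 m of the site is
returned verbatim (avoids division by near-zero), and a month no station
reports stays missing. Interpolated values are bounded by the contributing
stations' range by construction.

The SPI at scale k labels each month with the backward-looking k-month
precipitation sum. Per calendar month, a gamma distribution is fitted to
the positive sums within the calibration window (default: the full series;
a minimum of 20 calibration values per month is required, else that month
is left missing and logged). Shape and scale come from Thom's closed-form
maximum-likelihood approximation, `A = ln(x̄) − mean(ln x)`,
`α = (1 + √(1 + 4A/3)) / (4A)`, `β = x̄/α`, with a method-of-moments
fallback if A is numerically nonpositive. Zero sums are handled as a point
mass with plotting-position probability `q = n_zero/(n + 1)` (bounded away
from 0 and 1), giving the mixture `H(x) = q + (1−q)·G(x)` and
`SPI = Φ⁻¹(H)`, clipped to ±~6.4 by an ε of 1e−10 on H. A calendar month
whose sums are constant (variance below 1e−12) maps to SPI 0. SPI is
monotone in the aggregated sum within a calendar month.

Sampling note: on a 40-year series each calendar month contributes ~40
values, so the per-month *median* of the SPI has Monte-Carlo noise of
roughly 0.12–0.2 SD even for a perfect implementation. Normalization checks
therefore average the per-month median and SD over replicate series of the
same length; the averaged medians are within a few hundredths of 0 and the
averaged SDs near 1.01.

Drought years can be detected (any growing-season month, default April–
September, below a threshold, default −1.5, at any requested scale, default
{1, 3}; severity classifies the yearly minimum with strict thresholds
−1/−1.5/−2) — but event selection in real trials weighs growth impact and
cross-site coincidence, so a curated event list always overrides detection
and detection is advisory.

## Resistance and recovery

For tree i and event year e, resistance is `Res = I_dr / I_9yr` with
`I_9yr` the arithmetic mean of the 9-year window centred on e, *including*
the event year (the centred-window convention; a flag excludes it), and
recovery is `Rec = I_postdr / I_dr` over the 2 post-event years. Both are
computed on raw widths: within a 9-year window the age trend is negligible,
and dimensional transforms (e.g. basal-area increment) would change trait
variances and hence the downstream genetic parameters. Records are missing
— with a recorded reason — when the window is incomplete or contains
missing widths, and flagged degenerate when a ratio denominator is 0.
Overlapping windows of consecutive events are allowed and computed
independently; a record whose post-drought window contains another
configured event is flagged `biased_recovery` but still computed. Res and
Rec are invariant to rescaling a tree's widths and to anything outside
their windows.

## Finlay–Wilkinson stability

The environmental index of an event is the unweighted mean over provenance
means (each provenance mean over its trees' defined records), so unbalanced
tree counts do not tilt the baseline, and the focal provenance is included
— which makes the slopes of a complete provenance × event table average to
exactly 1, an identity the tests verify to 1e−10. Each provenance's event
means are regressed on the index by OLS; `b ≈ 1` is average stability,
`b > 1` unstable. Species summaries: `b_dev = mean |1−b|` over all
provenances; `b_ist` defaults to the mean of `|1−b|` over provenances with
`b > 1` (the "instability as deviation" reading), with the alternative
"mean of b over b > 1" selectable — the two circulate in the literature and
differ numerically, so both are implemented and the choice is recorded in
the output. With only 3 events slopes are noisy; `n_events` is always
reported and fits on fewer than 4 events log a warning. Rank stability is
the Spearman correlation (average ranks for ties) of provenance means
between event pairs, flagged low-power below 3 provenances.

## Variance components, repeatability, evolvability

Responses are natural-log-transformed and z-scored (sample SD, n−1) before
variance-component estimation; ratio traits are right-skewed and the
transform record is kept for invertibility. The order (log, then
standardize) is recorded; note r itself is invariant to the affine part.

Two random-effect designs are fitted by direct maximization of the profiled
restricted log-likelihood over variance ratios:

* tree intercepts only (per-provenance repeatability), where the grouped
  structure gives Sherman–Morrison closed forms per tree —
  `Σ_g^{-1} = I − λ/(1+n_g λ)·J` — and the profile is maximized by bounded
  scalar search on log λ (three deterministic brackets plus the λ = 0
  boundary, xatol 1e−12);
* provenance + tree intercepts, trees nested (species repeatability), with
  small dense per-provenance solves and L-BFGS-B over the two ratios from
  three deterministic starts.

Negative components are truncated at 0 and flagged boundary. The asymptotic
covariance of the components is the inverse finite-difference
observed-information matrix of the restricted log-likelihood at the
optimum; `se(r)` follows by the delta method for `r = σ²_A/(σ²_A + σ²_W)`.
Boundary estimates report `r = 0` (or 1 when the residual variance is 0,
e.g. identical repeats within every tree) with SE 0; significance is
`r/se > 1.96` by default. On balanced data with interior optima the REML
estimates equal the classical mean-squares estimators
(`σ̂²_W = MSW`, `σ̂²_A = (MSA − MSW)/k`) to ~1e−7, and both the single and
nested fits agree with statsmodels `MixedLM` to several decimals — the
tests keep that cross-check.

Species-level repeatability separates provenance variance (reported, but
excluded from the denominator), so r stays the among-tree fraction of the
within-provenance phenotypic variance. With provenance effects present and
ignored, a tree-only model would absorb them into the tree component — the
nested model is the estimator that targets the generative r.

Evolvability: `V_A = r·V_P` and `CV_A = 100·√V_A / X̄`, with `V_P` the
sample variance of the *raw-scale* trait over the provenance's tree-event
records and `X̄` the provenance trait mean — the conventional formula chain
pairs the transformed-scale r with raw-scale V_P, and this is deliberate
and documented rather than hidden. CV_A is scale-invariant; r is an upper
bound of h², so CV_A is an upper bound of the mean-standardized
evolvability.

Species comparisons use a fixed-effects two-way ANOVA (species × drought
year, with interaction) on individual-tree records (statsmodels OLS,
type-II sums of squares; sequential and partial coincide on balanced data)
and Tukey-HSD pairwise tests summarised as a compact letter display
(insert-and-absorb). The stepwise within-species sequence — intercept,
+drought, +provenance, +drought×provenance, each with a tree random
intercept — is fitted by **ML** (fixed-effect likelihood-ratio tests are
invalid under REML), with parameter counts of fixed effects plus the two
variance components (the intercept model therefore has 3), AIC = 2k −
2·logLik, and χ² p-values on parameter-count differences. All reported
variance components elsewhere use REML.

## Synthetic data generator

The generator emulates the target study design: 11 provenances × 16 trees
(9–16 provenances and ~16 trees per provenance is the realistic range),
annual rings 1971–2010, drought events 1993/2000/2003, and four stations of
monthly gamma precipitation (shape 1.6, ~540 mm/yr with a summer maximum)
with dry spells (factor 0.3, April–September) in 1992/1993/2000/2003.

Direct response draws follow `log y = μ + P_p + A_i + ε_ie` with
`P ~ N(0, 0.10²)`, `A ~ N(0, 0.15²)`, `ε ~ N(0, 0.25²)`, so the true
repeatability is `r_true = sA²/(sA² + sW²) ≈ 0.26` — inside the range
reported for conifer drought traits. An optional deterministic per-event
offset adds a drought main effect for power studies. Ring widths multiply a
negative-exponential age trend (2.5·exp(−0.04·t) + 1.0 mm), a lognormal
tree growth factor (SD 0.15), lognormal year noise (SD 0.15), and per-event
multipliers `exp(−(0.5 + E_e + P_p + A_i + ε_ie))` with random event
severities `E_e ~ N(0, 0.15²)`; two cores per tree add lognormal noise (SD
0.03). All noise is lognormal so widths stay positive; every draw is
reproducible from the seed, and event draws use a separate stream so a
configuration without events is an exact counterfactual.

What passing tests on these data do *not* show about real collections: no
spatial or temporal autocorrelation among trees beyond the shared event
effects, no cross-dating error, no age-dependent variance, no missing-ring
clusters, and provenance effects act on drought response only, not on
baseline growth. The ring-width pathway deliberately *attenuates* the
genetic signal relative to `r_true` — window dilution of A, shared event
effects inflating within-tree variance, and overlapping 2000/2003 windows
correlating residuals — so end-to-end checks assert monotonicity (more
tree-level sensitivity variance ⇒ higher estimated r) and generous bands,
while exact recovery is checked on the direct response draws. At realistic
scale a species-level boundary estimate (r̂ = 0) occasionally occurs; this
mirrors published trials and is reported as 0 ± 0 rather than suppressed.

## Problem sizes and tolerances

Monte-Carlo checks use: 500 trees × 3 events for recovery of
r ∈ {0, 0.15, 0.3, 0.45} (replicate-averaged over 3 seeds, band ±0.05);
200 replicates at 16 trees for SE calibration (delta SE within a factor 1.3
of the empirical SD of r̂) and for the null calibrations (provenance step
and repeatability significance each rejecting in ≤ 10% at α = 0.05);
50 balanced datasets for REML/ANOVA equivalence at 1e−6; 100 random tables
for the mean-slope identity at 1e−10; 24 replicate 40-year series for SPI
normalization and one series for the 1e−6 oracle agreement. These sizes
keep the whole suite near a minute while leaving sampling error well inside
each band.

## Known limitations

No pedigree, so only repeatability (an upper bound of h²), not heritability
itself; no SPEI or temperature-based drought indices; no cross-dating
quality control; no resilience/relative-resilience indices; joint
significance testing of slope heterogeneity and AMMI/GGE decompositions are
out of scope. The likelihood-ratio test of σ²_A = 0 against the boundary
mixture ½χ²₀ + ½χ²₁ is noted as the more accurate alternative to the Wald
criterion but the default significance rule is the conventional
`r/se > 1.96`.
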