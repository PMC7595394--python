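# Methods

This note documents the models and procedures prairienet implements,
the defaults it ships, and what its synthetic benchmark can and cannot
show about real field data.

## Data model

Surveys are long tables keyed by (site, treatment, year, month, taxon)
with one value per record: an integer trap count for bees, a
transect-level mean proportional cover in [0, 1] for forbs (the
per-quadrat layer is deliberately not modelled; every analysis consumes
transect-level cover). Months are the four survey months May–Aug,
treated as ordered labels — nothing finer than monthly resolution is
represented. Missing (site, month, taxon) combinations mean "not
detected" and enter every wide view as zeros; trap and quadrat surveys
record absences implicitly, so absence-as-zero, not
missing-at-random, is the faithful reading. Validation is total: any
invariant breach (duplicate keys, fractional bee counts, cover outside
[0, 1], unregistered taxa, land-cover proportions not summing to 1)
raises a located error and is never silently repaired. Trap type
(vane/pan/net) is collapsed; nothing downstream uses it.

## Diversity

Hill numbers use the plug-in definitions (q=0 count of detected
species; q=1 `exp` of Shannon entropy; q=2 inverse Simpson). Rarefied
richness is the exact expectation under subsampling without replacement,
computed with log-gamma binomial ratios for stability. For q=1 and q=2
the interpolated value is a seeded Monte-Carlo expectation over
multivariate-hypergeometric subsamples (default 100 per grid point)
rather than the analytic Chao–Jost estimators: simpler, and directly
checkable against an exact enumeration oracle at small n. Extrapolated
richness approaches `S_obs + f0·(1 − (1 − f1/(n·f0 + f1))^{m−n})` with
the bias-corrected undetected-species estimate
`f0 = ((n−1)/n)·f1²/(2f2)` (or the f2 = 0 variant); q=1 and q=2 are
held at the plug-in estimate beyond n. Extrapolation past 2n is refused
(points dropped with a warning): long-range extrapolation of asymptotic
richness is not trustworthy, and short extensions are all a treatment
comparison needs.

Confidence bands are percentile bootstrap (default 200 replicates) over
individuals: counts are resampled multinomially at fixed n, the whole
curve recomputed per replicate, and the 2.5/97.5 percentiles taken. The
interval is clamped to bracket the point estimate. Known bias: for q=0
the multinomial resample loses rare species, so the upper band can
collapse onto the point estimate at large m — the bands are honest for
comparison widths but slightly downward-shifted for richness.

## Community structure

Commonness is a study-wide quantity: a taxon is common iff its share of
all individuals over every site, treatment, year and month strictly
exceeds the threshold (default 1%). The pooled taxonomic aggregate can
be excluded from the candidate set (the "8-common" reading, which
guards against the aggregate masking other species) or classified like
any taxon ("9-common"); the denominator always includes it.

Bray–Curtis distances are computed between sampling events
(site×treatment×year×month species profiles). MRPP uses group weights
`C_g = n_g/N` (the common default in the field's software),
`δ = Σ_g C_g · mean within-group distance`, and a seeded Monte-Carlo
permutation distribution (default 9999 relabellings;
`p = (1 + #{δ* ≤ δ_obs})/(n_perm + 1)`), with an exhaustive enumeration
mode for small unit counts that the tests use as an oracle.
`T = (δ_obs − mean δ*)/sd δ*` and `A = 1 − δ_obs/mean δ*`.

Multivariate dispersion embeds the distance matrix by Gower-centred
PCoA. Because Bray–Curtis is non-Euclidean, negative eigenvalues arise;
all axes are retained and squared distances to the group's spatial
centroid are corrected by subtracting the imaginary-axis contributions
(the standard betadisper convention), clamping at zero before the square
root. Group spreads are compared by one-way ANOVA on the per-unit
distances (parametric p; an optional permutation p reshuffles labels
over the distance vector). Units are sampling events; the alternative
reading that disperses species profiles is not the default because the
event-level reading is the standard, testable one. Whether the original
field analysis pooled years or ran per year is unknowable from the
outside; the default pools.

## Co-occurrence network

The pairing unit is (site, month, year) over strip fields only — cover
is surveyed inside the strips — giving up to 32 paired observations per
bee×forb pair at the default design. Series align on the pairing keys
present in both tables, with absences as zeros. A cell is defined only
if both series are non-constant and n ≥ 3; undefined cells are flagged,
excluded from the BH family size, and can never be selected. p-values
are two-sided from the t transform on n−2 df; the positivity requirement
is applied as a separate sign filter (r > 0) rather than folding into a
one-sided test, because selection states the two criteria independently.
Selection uses unadjusted p by default with BH-adjusted p available as
an option — the adjusted network is far sparser, and the package keeps
both so the choice can be justified by the visitation check rather than
baked in. The validation statistic correlates the network's r matrix
(not the binary mask; the mask variant is exposed as an option) against
the raw visitation counts over defined cells. Monthly networks rebuild
the screen within each month on (site, year) pairings — 8 samples at the
default design — and aggregate selected species links to plant-family ×
bee-family weights; months with fewer than 3 samples are skipped with a
warning. Family-proportion totals are computed from unrounded
proportions and rounded last, so the grand total is exactly 1 whenever
any link is selected.

## Synthetic generator

The generator is the benchmark's definition of "realistic", chosen once:

- Design: 4 sites × {strip, control} × 2 years × 4 months = 64 events;
  89 bee taxa (88 species + 1 pooled aggregate), 55 forbs (27 native
  prairie, 28 exotic/weedy) spread over the field-typical family
  structure (Asteraceae and Fabaceae speciose and dominant in cover).
- Bee counts: Poisson on a log link,
  `log μ = base_b + 0.45·1[strip] + month_m + Σ_p β_bp·cover_p·1[strip]`,
  month multipliers (−0.3, 0.1, 0.5, 0.2) peaking in July. Baselines are
  lognormal(ln 0.034, 2.2) per event — steep enough that realized
  relative abundances straddle the 1% boundary (typically ~8–18 of 89
  taxa common). The pooled aggregate's baseline is 0.72× the summed
  species baselines (≈40% of the catch) and is drawn as the sum of five
  latent Poisson species, reproducing the masking behaviour of a
  taxonomically intractable subgenus.
- Cover: per event, a Dirichlet composition with lognormal(−1.1, 1.0)
  concentrations scaled by 0.6 total cover, so a handful of forbs
  dominate and per-species cover stays in [0, 1].
- Couplings: 25 planted β ~ U(8, 15) between high-baseline bees and
  high-cover forbs; on this cover scale β·sd(cover) ≈ 0.3–0.5, which a
  direct Monte-Carlo oracle puts at ≥0.9 selection power at n = 32 for
  the stronger pairs. Visits are Poisson with mean
  `120 · max(β, 0) · mean cover`, so the visitation matrix is consistent
  with the planted couplings and zero elsewhere.
- Land cover: total non-crop share uniform in [0.08, 0.69] (the range
  spanning simple to complex agricultural landscapes), split among
  non-crop classes by a flat Dirichlet.

What it does **not** emulate: spatial foraging, within-season
population dynamics, trap-type effects, observation error in cover
estimation, and phenology of flowering (cover composition has no month
trend). Passing recovery tests therefore show the statistical machinery
works at the study's dimensionality and noise level, not that the
screen's assumptions hold for any particular field system.

## Null calibration of the screen: a real limitation

With couplings zeroed, the two-sided p < 0.05 rate over all defined
cells is ≈0.055 rather than 0.050, and the selected-link rate
(r > 0 and p < 0.05) is ≈0.05 rather than the α/2 = 0.025 a symmetric
null would give. Stratifying by detection frequency isolates the cause:
bees detected in ≥5 of the 32 strip events are calibrated (rate
0.049–0.051), while rarely detected species produce spike-like series
for which the t approximation runs liberal and for which a significant
correlation is almost inevitably positive — a single spike coinciding
with a cover outlier pushes r up, and with both variables bounded below
at zero there is no symmetric mechanism pushing r down. The bias is a
product of third moments: it vanishes when either series is symmetric.
Practical reading: on sparse, skewed abundance data a Pearson
co-occurrence screen over-selects positive links among rare species, so
rare-species links in such networks should be treated as candidates, not
evidence. The test suite asserts calibration on the well-populated
stratum and records the all-cells behaviour as-is.

## Numerical and reproducibility choices

Seeds: a single master seed determines every stochastic stage; per-stage
seeds derive from SHA-256 of `"{master}:{stage}"` (mod 2³¹), so stages
are individually reproducible. Fixed seed ⇒ byte-identical output files.
Permutation p-values use the add-one convention and a ≤ comparison with
a 1e-12 slack for float ties. Bray–Curtis between two all-zero events is
undefined and raises, naming the units. Log-means in the generator are
capped at 9 to keep extreme lognormal draws from overflowing Poisson
sampling. Eigenvalues within 1e-10 of zero are treated as null axes in
PCoA. Default problem sizes (9999 permutations, 200 bootstrap
replicates, 100 subsamples per interpolation point, 20–100 seed
replicates in the calibration and recovery suites) keep a full run on
one CPU in the minutes range while leaving Monte-Carlo error well inside
the asserted tolerances.
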