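# Methods

## The evaluation pipeline

The package analyses a standard post-weaning performance test: animals
in contemporary groups (same trial period and farm of origin) are fed
individually for a fixed test length, weighed on two consecutive days
at each boundary and every 14 d between, and optionally ultrasound
scanned for 12th-rib backfat (UBF) at the end of the test. The
analysis stages are data editing, per-animal growth summaries,
expected-intake regression, residual extraction and classification,
truncated-window comparison, and agreement statistics. Each stage is a
pure function of the input tables; the pipeline runner writes every
artifact with fixed float precision and LF newlines so a given
(config, seed) pair reproduces the bundle byte-for-byte, and the
`verify` subcommand recomputes and diffs it.

## Data editing

Three screens, applied in order: complete intake records (a DMI value
for every feeding day), the age window (at least 240 d at test start
and at most 390 d at completion, both inclusive), and total test
intake within ±4 sample SDs of the contemporary-group mean. The intake
screen recomputes group statistics on the survivors of the first two
edits, and the candidate animal is included in its own group's
mean/SD. That inclusive convention caps the attainable |z| at
(n−1)/√n, so a lone outlier can never be flagged in a group of 12
(max |z| ≈ 3.18) while the same outlier in a group of 46 (max
|z| ≈ 6.64) is removed; the cap is documented rather than "fixed"
because leave-one-out screening is a different statistic with
different small-group behaviour. A singleton group is retained with a
warning — the screen is undefined there.

## Growth metrics

ADG₁ is the OLS slope of weight on day over *all* weigh points,
including the duplicated boundary days (−1, 0, 69, 70); nothing in the
test design says which points enter the regression, and using all of
them is the maximal-information choice. ADG₂ divides the difference of
the two-day endpoint means by the nominal test length (70 d, not 71).
Mean DMI covers feeding days 1..D.

Metabolic midweight is `(final BW − 0.5·days·ADG)^0.75` with the
midweight in kg. Published per-group tables from comparable trials
print MMWT values consistent with exponentiating on the *pound* scale
and rescaling (≈66 rather than ≈81 kg^0.75 at typical weights); a
`legacy_lb_mode` flag reproduces that convention,
`(mw·2.20462)^0.75 / 2.20462`, for users matching such tables. The kg
formula is the default because it is the formula as written.

## RFI models and classification

The four expected-DMI models are fitted by OLS (statsmodels) on the
per-animal summary table. The default `fit_scope` is `pooled` — one
regression over all retained animals — because the model statements
contain no group term; `per_group` and `group_fixed_effect` scopes are
selectable for users who want contemporary group absorbed into the
fit. Animals without a UBF record are dropped only from the
backfat-adjusted models; the unadjusted models keep them, so the two
n's can differ.

Classification uses the within-group sample SD (n−1) of the model
residuals with strict inequalities: exactly ±1 SD is medium. Under
normality this yields expected class proportions Φ(−1) ≈ 0.159 /
0.683 / 0.159, which the tests check on 10,000 standard-normal
residuals. A zero-SD group classifies everyone medium.

Class summaries are raw arithmetic means ± SEM per class, labelled
unadjusted: the multi-factor least-squares-means analysis (farm, sire,
trial effects) is out of scope, and presenting raw means as LS-means
would be misleading.

## Test-duration analysis

For each truncated duration d ∈ {14, 28, 42, 56}, summaries are
recomputed with the single day-d weight as "final BW" (no
consecutive-day pair exists mid-test), ADG₁ refitted on points ≤ d,
and mean DMI over days 1..d. Because the two-day initial mean is
centred at day −0.5, the truncated ADG₂ spans d + 0.5 days over a
d-day denominator; this small multiplicative bias, (d+0.5)/d, is
inherent to the endpoint definition and is asserted exactly in the
zero-noise tests rather than corrected. RFI at each duration is the
residual of a model refitted on that duration's own ADG/MMWT/DMI — not
a truncation of the 70-d residuals. Full-test values are regressed on
truncated values (slope, SE, R²) with Pearson and Spearman
correlations; the d-day window is nested in the full window by design,
and no overlap correction is applied, matching how shortened-test
studies in this field report these statistics. Correlation p-values
use the t-approximation; exact permutation p-values are available via
a flag for small n.

## Agreement statistics

Cohen's kappa is implemented from the confusion-matrix formulas (module
docstring spells them out) with the Fleiss–Cohen–Everitt asymptotic
variance for the CI and the null-hypothesis variance for the z-test;
identity weights give the unweighted statistic and linear
Cicchetti–Allison weights (the default of the SAS AGREE procedure) the
weighted one, with quadratic weights as an option. The implementation
is cross-checked in the tests against statsmodels'
`cohens_kappa` — an independent route to the same statistic — and both
weighted and unweighted values are always reported, since published
kappas rarely state which was used. Confusion-matrix category order is
fixed low < medium < high regardless of input order.

## The synthetic generator

The generator defines the study conditions for every downstream test:
seven contemporary groups of 20/46/22/23/22/12/41 animals (186 total)
across two farms, with group-level initial-BW and ADG means/SDs at the
levels of a southeastern U.S. Brangus heifer test (initial BW ≈
278–325 kg, ADG ≈ 1.19–1.61 kg/d). Each animal's latent mean intake is

    mean DMI = −0.5 + 1.8·ADG + 0.105·MMWT + 0.05·UBF + true_rfi

with `true_rfi ~ N(0, 0.95 kg/d)`. The coefficients are configuration,
not biological claims; at these levels they produce mean DMI of
~9.7–12 kg/d and a pooled base-model R² near 0.48, inside the
0.40–0.65 band that brackets published heifer-test fits. Daily intake
adds N(0, 1.5 kg/d) day-to-day noise (roughly a 15% CV, typical of
individual-feeding systems); weighings add N(0, 4 kg) scale noise
(≈1% of BW, gut-fill scale). UBF is drawn once per animal (end-of-test
scan) from a bivariate-normal construction with correlation 0.25 to
the true efficiency residual — the weak fat–efficiency coupling
reported across the literature. Ages on test are drawn inside the
240–320 d window so default rosters pass the age screen.

Randomness uses one root seed with per-animal substreams keyed on
(seed, animal index), so appending a group never perturbs earlier
animals and identical (config, seed) runs are byte-identical.

What the generator does *not* emulate: persistent within-animal intake
drift (illness, weather, feeding-order effects), growth curvature,
pen/social effects, orts accounting, or missing-data patterns. Daily
intakes are i.i.d. around the animal mean, so short-window intake
means track the full-test mean more tightly than they do in real
trials — truncated-window correlations here are optimistic upper
bounds, and passing the qualitative duration tests (correlations
nondecreasing in window length; gain noisier than intake at 14 d) does
not certify any particular correlation level in real data. Weights are
exactly linear in time apart from i.i.d. noise, so ADG₁ ≈ ADG₂ by
construction.

## Numerical choices and degenerate inputs

- OLS everywhere is either `numpy.polyfit` (single predictor) or
  statsmodels (multiple); rank deficiency raises an error naming the
  collinear columns rather than silently pseudo-inverting.
- Residual sums per fitted scope are checked to 1e-8·n; residuals are
  orthogonal to predictors to 1e-6·n·scale.
- Constant vectors make correlations and slopes undefined errors, not
  NaN propagation; a degenerate kappa (both raters constant on the
  same label) raises rather than returning 0/0.
- Generated CSV values are rounded to 4 decimals for byte-stable
  output; zero-noise recovery tests therefore assert at 1e-3.
- Ages are whole-day date differences; no timezone handling.
- Default problem sizes (186 animals, 70 d, 20-seed replication for
  the duration-pattern property) keep the full suite and the
  acceptance script in the tens of seconds on one core.

## Known limitations

- The exclusive-vs-inclusive outlier screen and the pooled-vs-grouped
  fit scope are genuine analysis choices on which published reports
  are often silent; both alternatives are exposed as options, and the
  defaults are the simplest reading of standard practice.
- Raw class means are not least-squares means; with unbalanced farms
  or sires they will differ from a GLM-adjusted analysis.
- The generator's linear growth and i.i.d. intake noise make the
  duration analysis qualitatively, not quantitatively, comparable to
  real trials (see above).
- Genetic parameters (heritability, EBV/EPD) are out of scope; this is
  a phenotypic evaluation package.
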