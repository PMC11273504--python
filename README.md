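# rfitrial

Residual-feed-intake (RFI) evaluation for cattle performance tests, built
around the workflow of a multi-group heifer feed trial: data editing,
growth metrics, expected-intake regression models, efficiency
classification, test-duration analysis, and model-agreement statistics.
It is aimed at animal scientists and performance-test operators who want
a reproducible, scriptable version of the analysis that is usually run
ad hoc in SAS or R, plus a seeded synthetic-trial generator for method
development when real intake data are unavailable.

## The model

RFI is the residual of an ordinary-least-squares regression of observed
dry-matter intake (DMI, kg/d) on average daily gain and metabolic
midweight — the feed an animal consumes beyond what its growth and
maintenance predict. Negative RFI = efficient; positive = inefficient.
Gain is measured two ways:

- **ADG₁** — the OLS slope of body weight on day of test over all weigh
  points (weighings at days −1, 0, every 14 d, and the terminal pair);
- **ADG₂** — (final BW − initial BW) / days on test, each endpoint the
  mean of two consecutive-day weighings.

Metabolic midweight scales mid-test body weight by the classical 0.75
power of maintenance metabolism, `MMWT = (final BW − 0.5·days·ADG)^0.75`,
computed once with each ADG. Four model variants cross the ADG
definition with an optional ultrasound 12th-rib backfat covariate (UBF):

```
RFI_1  : DMI ~ ADG1 + MMWT1            RFI_bf1 : DMI ~ ADG1 + MMWT1 + UBF
RFI_2  : DMI ~ ADG2 + MMWT2            RFI_bf2 : DMI ~ ADG2 + MMWT2 + UBF
```

Animals more than 1 SD from their contemporary-group mean RFI are
classed low/high; the rest medium. Agreement between model pairs is
quantified with Pearson/Spearman correlations, regression-equivalence
(slope CI containing 1), and Cohen's kappa (unweighted and
linear-weighted, with asymptotic SEs implemented from the
confusion-matrix formulas). The duration module recomputes every metric
on truncated windows (14/28/42/56 d) and regresses full-test values on
them to ask how short a test can get before animal rankings drift.

## Worked example

```bash
python examples/03_rfi_models_and_classes.py
```

```
RFI_1: R^2 = 0.482, n = 186
RFI_bf1: R^2 = 0.516, n = 186
RFI_2: R^2 = 0.481, n = 186
RFI_bf2: R^2 = 0.515, n = 186

corr(true simulated RFI, fitted RFI_1) = 0.970
class counts: {'medium': 132, 'high': 28, 'low': 26}

class mean DMI (kg/d):
low        9.40
medium    10.75
high      12.50
```

The four fits explain ~48–52% of intake variation (the backfat
covariate adds ~3 points), the fitted residuals correlate 0.97 with the
generator's true efficiency values, and high-RFI heifers ate 33% more
feed per day than low-RFI heifers at the same gain — the economic
signal RFI selection targets. The other scripts in `examples/` walk the
remaining capabilities (simulation, QC + growth, duration analysis,
agreement statistics).

The same pipeline runs from a shell:

```bash
rfitrial run --seed 1 --out results_dir      # simulate + full analysis
rfitrial run --input-dir my_trial/ --out out # or your own CSVs
rfitrial verify --seed 1 --out results_dir   # byte-identical recompute check
```

Input CSVs are `heifers.csv` (id, group, farm, birth_date, on_test_date,
days_on_test, ubf_mm), `intake.csv` (id, day, dmi_kg) and `weights.csv`
(id, day, bw_kg), with ISO dates and days counted from on-test day 0.

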