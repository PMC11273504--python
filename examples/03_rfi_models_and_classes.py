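"""Fit the four expected-DMI models, extract RFI, and classify animals.

RFI is the residual of observed intake after regressing on gain and
metabolic midweight: negative = efficient (eats less than growth and
maintenance predict), positive = inefficient.  Animals more than 1 SD
from their contemporary-group mean are labelled low/high; the rest
medium.
"""

import numpy as np

from rfitrial.growth import summarize_cohort
from rfitrial.qc import run_qc
from rfitrial.rfi import class_summary, classify_rfi, compute_rfi_models
from rfitrial.simulate import default_config, generate_trial

trial = generate_trial(default_config(), seed=1)
days = int(trial.heifers["days_on_test"].max())
kept = run_qc(trial.heifers, trial.intake, required_days=days).retained_ids
table = summarize_cohort(trial.heifers, trial.intake, trial.weights, kept)

fits = compute_rfi_models(table)
for name, fit in fits.items():
    print(f"{name}: R^2 = {fit.r_squared:.3f}, n = {fit.n}")

fit1 = fits["RFI_1"]
truth = trial.truth.set_index("id").loc[fit1.residuals.index, "true_rfi"]
print(f"\ncorr(true simulated RFI, fitted RFI_1) = {np.corrcoef(truth, fit1.residuals)[0, 1]:.3f}")

groups = table.set_index("id")["group"]
cls = classify_rfi(fit1, groups)
print("class counts:", dict(cls.labels.value_counts()))

summary = class_summary(table, cls, fit1)
print("\nclass mean DMI (kg/d):")
print(summary["mean"]["mean_dmi"].round(2).to_string())
print(
    f"\nhigh-RFI heifers ate {summary.attrs['dmi_excess_pct']:.0f}% more feed per day than\n"
    "low-RFI heifers while gaining at the same rate - that gap is the\n"
    "economic signal RFI selection targets."
)
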