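"""Would a shorter test rank animals the same way as the full 70 days?

Each metric is recomputed on truncated windows (14/28/42/56 d) and the
full-test value is regressed on the truncated one; Pearson/Spearman
correlations measure how much of the 70-d ranking the shorter window
already contains.  RFI at each duration is refitted on that window's
own summaries, not truncated from the 70-d residuals.
"""

from rfitrial.duration import duration_table
from rfitrial.qc import run_qc
from rfitrial.simulate import default_config, generate_trial

trial = generate_trial(default_config(), seed=1)
days = int(trial.heifers["days_on_test"].max())
kept = run_qc(trial.heifers, trial.intake, required_days=days).retained_ids

table = duration_table(
    trial.heifers,
    trial.intake,
    trial.weights,
    durations=(14, 28, 42, 56),
    metrics=("mean_dmi", "adg1", "rfi1"),
    ids=kept,
)
cols = ["metric", "duration_d", "slope", "r_squared", "pearson", "spearman"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nIntake stabilizes quickly (high DMI correlations even at 14 d) while\n"
    "gain needs longer windows: the weakest link for shortening a test is\n"
    "the ADG estimate, not the intake record."
)
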