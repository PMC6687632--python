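"""Small sensitivity grid of the additive simulation model.

Sweeps the number of planted features per class (G) and the expression
tail width (T) on a reduced cohort and reports the mean fraction of
planted features the pipeline recovers.  The full-scale grid (800
subjects, 20+ replicates) is what scripts/acceptance.py runs.
"""

from sigassoc import run_grid

grid = run_grid(
    g_values=[2, 5],
    t_values=[10.0, 20.0],
    n_replicates=3,
    seed=0,
    n_subjects=300,
    n_background_features=100,
    planted_prevalence=0.1,
)
cols = ["G", "T", "mean_sensitivity", "mean_mutation", "mean_cna",
        "mean_over_expression", "mean_under_expression"]
print(grid[cols].round(3).to_string(index=False))
print("\nmean_sensitivity = fraction of the 4G planted features called "
      "significant at the default cutoffs, averaged over replicates")
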