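"""Screen concomitant medications and build their trajectory scores.

After cohort selection, each candidate co-medication is screened with a
Wilcoxon rank-sum test (ever-on vs never-on against the HbA1c change)
with Benjamini-Hochberg FDR control; medications passing q < 0.05 are
trajectory-scored and their score distribution tabulated.
"""

from conmedscore import (
    SimulationConfig,
    score_distribution,
    score_table,
    screen_conmeds,
    select_primary_cohort,
    simulate_trial,
)

cfg = SimulationConfig(n_subjects=1500, seed=11)
ds, _, truth = simulate_trial(cfg)
cohort = select_primary_cohort(ds, cfg.primary_medication, cfg.phenotype)
print(f"cohort: {len(cohort.included)} subjects\n")

screening = screen_conmeds(cohort, ds, list(cfg.conmeds))
print("screen (ever-on vs never-on, q < 0.05):")
print(screening.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

selected = screening.loc[screening["selected"], "medication"].tolist()
windows = {w.subject_id: w for w in cohort.included}
scores = score_table(ds, windows, selected, include_insulin=True)
print("\nscore distribution for selected conmeds (columns are scores 0-4):")
print(score_distribution(scores, selected).to_string(index=False))
print("\ninsulin is summarized as a continuous dose change (units/day):")
print(scores["insulin_delta"].describe().round(2).to_string())
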