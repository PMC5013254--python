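"""Score the five canonical concomitant-medication trajectories.

Builds one synthetic subject per scenario — varying only when the
co-medication starts and stops relative to a primary-medication
treatment window starting at day 100 (window 90-270 days) — and prints
the 0-4 trajectory score the monthly scorer assigns.
"""

import numpy as np
import pandas as pd

from conmedscore import TrialDataset, score_monthly_conmed
from conmedscore.cohort import PhenotypeObs, TreatmentWindow

START = 100
WINDOW = TreatmentWindow(
    "S1", "primary_med", START,
    PhenotypeObs("S1", START - 5, "hba1c_pct", 8.0),
    PhenotypeObs("S1", START + 100, "hba1c_pct", 7.0),
)

SCENARIOS = {
    "never on the co-medication": [],
    "on before window start, stops at window day 120": range(40, 221, 30),
    "starts at window day 30, stops at window day 120": range(130, 221, 30),
    "starts at window day 30, compliant to window end": range(130, 371, 30),
    "on before window start, compliant to window end": range(40, 371, 30),
}

for label, days in SCENARIOS.items():
    rows = [("S1", START, "primary_med", 1, np.nan)]
    rows += [("S1", d, "conmed", 1, np.nan) for d in days]
    med = pd.DataFrame(rows, columns=["subject_id", "day", "medication",
                                      "compliance", "insulin_units_per_day"])
    med["compliance"] = med["compliance"].astype("Float64")
    ds = TrialDataset(
        med_logs=med,
        annual_logs=pd.DataFrame(columns=["subject_id", "day", "medication_class", "on_flag"]),
        phenotypes=pd.DataFrame(columns=["subject_id", "day", "phenotype", "value"]),
        baselines=pd.DataFrame({"subject_id": ["S1"]}),
    )
    score = score_monthly_conmed(ds, "S1", "conmed", WINDOW)
    print(f"score {score.value}: {label}")

print("\nScores 1/4 mean the subject was already on the drug at window start;")
print("3/4 additionally require full compliance through the window end.")
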