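import numpy as np
import pandas as pd
import pytest

from conmedscore.cohort import PhenotypeObs, TreatmentWindow
from conmedscore.trial_data import TrialDataset


def make_dataset(med_rows=(), annual_rows=(), pheno_rows=(), baseline_ids=None, class_map=None):
    """Build a TrialDataset from terse row tuples.

    med_rows: (subject_id, day, medication[, compliance[, insulin_units]])
    annual_rows: (subject_id, day, medication_class, on_flag)
    pheno_rows: (subject_id, day, phenotype, value)
    """
    med = pd.DataFrame(
        [(r[0], r[1], r[2],
          r[3] if len(r) > 3 else np.nan,
          r[4] if len(r) > 4 else np.nan) for r in med_rows],
        columns=["subject_id", "day", "medication", "compliance", "insulin_units_per_day"],
    )
    med["compliance"] = med["compliance"].astype("Float64")
    ann = pd.DataFrame(list(annual_rows),
                       columns=["subject_id", "day", "medication_class", "on_flag"])
    ph = pd.DataFrame(list(pheno_rows), columns=["subject_id", "day", "phenotype", "value"])
    if baseline_ids is None:
        baseline_ids = sorted(
            set(med["subject_id"]) | set(ann["subject_id"]) | set(ph["subject_id"])
        )
    base = pd.DataFrame({"subject_id": list(baseline_ids)})
    return TrialDataset(med, ann, ph, base, dict(class_map or {}))


def make_window(subject_id="S1", start=100, pre_val=8.0, post_val=7.0,
                phenotype="hba1c_pct", medication="primary_med"):
    return TreatmentWindow(
        subject_id, medication, start,
        PhenotypeObs(subject_id, start - 5, phenotype, pre_val),
        PhenotypeObs(subject_id, start + 100, phenotype, post_val),
    )


@pytest.fixture
def window():
    return make_window()
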