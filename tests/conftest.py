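import logging

import numpy as np
import pandas as pd
import pytest

from persym.simulate import SimulationSpec, generate_trial

logging.getLogger("persym").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_trial():
    """One seeded default trial shared by read-only tests."""
    return generate_trial(SimulationSpec(seed=20260904), seed=20260904)


# per-participant (baseline, month-6) scored values on the chosen instrument;
# literals so tests can hand-compute references and z independently
TINY_CHALDER = {"T1": (20, 18), "T2": (24, 15)}
TINY_MRC = {"T3": (3, 2), "T4": (5, 4)}
TINY_P4 = {"T5": (12, 10), "T6": (26, 20)}
TINY_HADS = {"T7": (18, 12), "T8": (30, 28)}
TINY_OTHER = {"T9": ("brain fog", 7.0, 5.0), "T10": ("insomnia", 4.0, 4.5)}


@pytest.fixture()
def tiny_cohort():
    """Ten hand-written participants, two per chosen-symptom stratum."""
    cohort = pd.DataFrame({
        "participant_id": [f"T{i}" for i in range(1, 11)],
        "arm": ["control", "intervention"] * 5,
        "chosen_symptom": ["fatigue", "fatigue",
                           "breathlessness", "breathlessness",
                           "pain", "pain",
                           "anxiety_depression", "anxiety_depression",
                           "other", "other"],
        "main_symptom_label": [None] * 8 + ["brain fog", "insomnia"],
        "sex": ["female"] * 8 + ["male", "female"],
        "age_band": ["<50", "50+"] * 5,
        "ethnicity": ["white"] * 9 + ["south_asian"],
        "imd_band": ["1-5", "6-10"] * 5,
    })
    scored_rows = []
    for month_idx, month in enumerate((0, 6)):
        for pid in cohort["participant_id"]:
            row = {"participant_id": pid, "visit_month": month,
                   "chalder_total": np.nan, "mrc_grade": np.nan,
                   "p4_total": np.nan, "hads_total": np.nan}
            if pid in TINY_CHALDER:
                row["chalder_total"] = TINY_CHALDER[pid][month_idx]
            if pid in TINY_MRC:
                row["mrc_grade"] = TINY_MRC[pid][month_idx]
            if pid in TINY_P4:
                row["p4_total"] = TINY_P4[pid][month_idx]
            if pid in TINY_HADS:
                row["hads_total"] = TINY_HADS[pid][month_idx]
            scored_rows.append(row)
    scored = pd.DataFrame(scored_rows)
    other_rows = []
    for pid, (label, v0, v6) in TINY_OTHER.items():
        other_rows.append((pid, 0, label, v0))
        other_rows.append((pid, 6, label, v6))
        other_rows.append((pid, 0, "headache", 3.0))  # tracked but not the main symptom
        other_rows.append((pid, 6, "headache", 2.0))
    other = pd.DataFrame(other_rows, columns=["participant_id", "visit_month",
                                              "symptom_label", "vas"])
    return cohort, scored, other
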