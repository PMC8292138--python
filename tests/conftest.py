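import numpy as np
import pandas as pd
import pytest

from diindex.reference import FoodParameterReference, ReferenceTable, load_reference_table
from diindex.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def reference():
    return load_reference_table()


@pytest.fixture()
def fiber_ref():
    # constants matching the bundled fiber row; handy for closed-form checks
    return FoodParameterReference("fiber", "g", 18.8, 4.9, -0.663)


@pytest.fixture()
def tiny_reference(fiber_ref):
    return ReferenceTable(
        [
            fiber_ref,
            FoodParameterReference("saturated_fat", "g", 28.6, 8.0, 0.373),
            FoodParameterReference("magnesium", "mg", 310.1, 139.4, -0.484),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable synthetic cohort (n=4,000) shared across read-only tests."""
    config = SyntheticConfig(n_participants=4_000, seed=2024)
    participants, truth = generate_cohort(config)
    return participants, truth


def make_participant(pid="P1", hf="yes", hypertension="yes", scorable=True, **kw):
    rec = {
        "participant_id": pid,
        "age": 60.0,
        "sex": "male",
        "bmi": 30.0,
        "heart_failure": hf,
        "hypertension": hypertension,
        "diabetes": "no",
        "prediabetes": "no",
        "coronary_artery_disease": "no",
        "angina": "no",
        "heart_attack": "no",
        "stroke": "no",
        "diet_scorable": scorable,
    }
    rec.update(kw)
    return rec


@pytest.fixture()
def ten_record_frame(reference):
    """Hand-enumerated flow fixture: 3 HF, 4 non-HF, 1 per exclusion reason."""
    rows = []
    intakes = {f"diet_{name}": reference[name].global_mean for name in reference.names}
    for i in range(3):
        rows.append({**make_participant(f"HF{i}", hf="yes"), **intakes})
    for i in range(4):
        rows.append({**make_participant(f"NH{i}", hf="no"), **intakes})
    rows.append({**make_participant("MISS_HF", hf=np.nan), **intakes})
    rows.append({**make_participant("NO_BASIC", hf="no", hypertension="no"), **intakes})
    rows.append(make_participant("MISS_DIET", hf="yes"))  # no diet columns filled
    frame = pd.DataFrame(rows).drop(columns=["diet_scorable"])
    return frame
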