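import pandas as pd
import pytest

from mealcontext import data_model as dm
from mealcontext import synthetic_data as sd


@pytest.fixture
def tiny_tables():
    """Hand-written three-participant raw tables (CSV-shaped)."""
    participants = pd.DataFrame({
        "participant_id": ["P1", "P2", "P3"],
        "age": [30, 45, 60],
        "sex": ["female", "male", "female"],
        "ethnicity": ["chinese", "malay", "indian"],
        "education": ["university", "a_level", "below_a_level"],
        "smoking": [False, True, False],
        "heavy_alcohol": [False, False, False],
        "working": [True, True, False],
        "married_or_partnered": [True, False, True],
        "bmi": [22.5, 27.1, 24.0],
        "glycemic_status": ["normal", "prediabetes", "normal"],
    })
    surveys = pd.DataFrame({
        "survey_id": ["S1", "S2", "S3", "S4"],
        "participant_id": ["P1", "P1", "P2", "P3"],
        "prompt_time": ["2024-01-01T08:30:00", "2024-01-01T13:40:00",
                        "2024-01-01T08:45:00", "2024-01-01T18:30:00"],
        "window_index": [1, 3, 1, 5],
        "stress": [1.0, 2.0, None, 3.0],
        "hunger": [2.0, 4.0, None, 1.0],
        "tiredness": [0.0, 3.0, None, 2.0],
        "happiness": [5.0, 4.0, None, 4.0],
        "rating_time": ["2024-01-01T08:30:10", "2024-01-01T13:40:05",
                        None, "2024-01-01T18:30:20"],
    })
    meals = pd.DataFrame({
        "meal_id": ["M1", "M2", "M3"],
        "participant_id": ["P1", "P1", "P3"],
        "survey_id": ["S1", "S2", "S4"],
        "eat_time": ["2024-01-01T08:00", "2024-01-01T13:00",
                     "2024-01-01T19:00"],
        "food_groups": ["refined_grains|vegetables", "whole_grains|seafood",
                        ""],
        "location": ["home", "hawker", "other_restaurant"],
        "companions": ["alone", "spouse|children", "friends"],
        "activities": ["nothing", "talking", "leisure_screen|talking"],
        "fullness": [4, 3, 5],
    })
    cgm_times = pd.date_range("2024-01-01 06:00", periods=60, freq="15min")
    cgm = pd.DataFrame({
        "participant_id": "P1",
        "timestamp": cgm_times.strftime("%Y-%m-%dT%H:%M:%S"),
        "glucose_mmol_l": 5.0,
    })
    return {"participants": participants, "surveys": surveys,
            "meals": meals, "cgm": cgm}


@pytest.fixture
def tiny_dir(tiny_tables, tmp_path):
    for name, df in tiny_tables.items():
        df.to_csv(tmp_path / f"{name}.csv", index=False)
    return tmp_path


@pytest.fixture
def tiny_bundle(tiny_dir):
    return dm.load_tables(tiny_dir / "participants.csv",
                          tiny_dir / "surveys.csv",
                          tiny_dir / "meals.csv",
                          tiny_dir / "cgm.csv")


@pytest.fixture(scope="session")
def default_cohort():
    """One 500-participant cohort at the default (study-condition)
    parameters, with rendered CGM; shared across calibration checks."""
    cfg = sd.SimulationConfig(n_participants=500, seed=97)
    return sd.simulate_cohort(cfg)
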