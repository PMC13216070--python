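"""Shared fixtures: small synthetic worlds and survey-schema tables."""

import numpy as np
import pandas as pd
import pytest

from wildmeat.model import sim_design
from wildmeat.survey import ingest_tables
from wildmeat.synthetic import (
    GenerativeParams,
    LandscapeSpec,
    ObservationSpec,
    generate_landscape,
    observe,
    simulate_truth,
)

TINY_SPEC = LandscapeSpec(n_side=10, region_rows=(4, 2, 4))


@pytest.fixture(scope="session")
def tiny_world():
    """A 100-cell landscape with a surveyed campaign: fast shared input."""
    landscape = generate_landscape(TINY_SPEC, seed=11)
    truth = simulate_truth(landscape, GenerativeParams(), seed=12)
    tables = observe(
        truth,
        ObservationSpec(coverage=0.20, household_sampling_fraction=0.15),
        seed=13,
    )
    return {"landscape": landscape, "truth": truth, "tables": tables}


@pytest.fixture(scope="session")
def tiny_model_data(tiny_world):
    t = tiny_world["tables"]
    tables = ingest_tables(
        t["studies"], t["locations"], t["households"], t["recalls"]
    )
    return sim_design(tables)


@pytest.fixture(scope="session")
def survey_schema_tables():
    """Hand-built tables in the real survey schema (HPD/REM/HDI/FCI,
    settlement types, education, study types, periods)."""
    rng = np.random.default_rng(21)
    n_loc = 12
    studies = pd.DataFrame(
        {
            "study_id": ["s1", "s2", "s3"],
            "study_type": [1, 2, 3],
            "period": [1, 2, 2],
        }
    )
    locations = pd.DataFrame(
        {
            "location_id": [f"L{i}" for i in range(n_loc)],
            "lon": rng.uniform(10, 20, n_loc).round(3),
            "lat": rng.uniform(-5, 5, n_loc).round(3),
            "location_type": ["village"] * 8 + ["town"] * 3 + ["city"],
            "hpd": rng.uniform(1, 500, n_loc).round(1),
            "rem": rng.uniform(0, 10, n_loc).round(2),
            "hdi": rng.uniform(0.3, 0.7, n_loc).round(3),
            "fci": rng.uniform(0, 1, n_loc).round(3),
            "study_id": ["s1"] * 4 + ["s2"] * 4 + ["s3"] * 4,
        }
    )
    households = []
    recalls = []
    rid = 0
    for i in range(n_loc):
        for j in range(6):
            hid = f"H{i}_{j}"
            mdays = int(rng.integers(2, 30))
            ame = float(rng.integers(1, 9)) if j != 5 else np.nan
            households.append(
                {
                    "household_id": hid,
                    "location_id": f"L{i}",
                    "mdays": mdays,
                    "frequency": float(rng.uniform(0.02, 0.6)) if j < 4 else np.nan,
                    "education": ["primary_or_none", "secondary_or_higher",
                                  "unknown"][j % 3],
                    "ame": ame,
                }
            )
            for _ in range(3):
                consumed = int(rng.random() < 0.3)
                q = float(rng.gamma(2.0, 0.4)) if consumed else 0.0
                recalls.append(
                    {
                        "recall_id": f"r{rid}",
                        "household_id": hid,
                        "days": float(rng.integers(1, 8)),
                        "consumed": consumed,
                        "quantity_kg": q,
                        "ame": ame,
                    }
                )
                rid += 1
    return {
        "studies": studies,
        "locations": locations,
        "households": pd.DataFrame(households),
        "recalls": pd.DataFrame(recalls),
    }
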