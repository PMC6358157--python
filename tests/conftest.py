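"""Shared fixtures: small synthetic tables and row builders."""

import numpy as np
import pandas as pd
import pytest

from socisol import synthetic as syn
from socisol.scoring import CHRONIC_COLUMNS, PARTICIPATION_COLUMNS


def make_participant(**overrides) -> dict:
    """A fully-connected, healthy default participant row."""
    row = {
        "participant_id": "P000001",
        "fsa_code": "R3T",
        "age_years": 50,
        "sex": "woman",
        "marital_status": "married_commonlaw",
        "household_size": 3,
        "contact_children": 1,
        "contact_siblings": 1,
        "contact_close_friends": 1,
        "contact_neighbors": 1,
        "retired": "working",
        "cesd_lonely": 4,
        "education": "postsecondary",
        "income_band": "50to100k",
        "functional_level": "none",
        "urban_rural": "urban_core",
        "weight": 1.0,
    }
    for c in PARTICIPATION_COLUMNS:
        row[c] = 2
    for c in CHRONIC_COLUMNS:
        row[c] = 0
    row.update(overrides)
    return row


def participant_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([make_participant(**r) for r in rows])


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully-featured synthetic dataset with ground truth."""
    cfg = syn.SimulationConfig(n_fsa=80, cluster_size_mean=30, seed=20240917)
    participants, census, truth = syn.generate_tables(cfg)
    return cfg, participants, census, truth
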