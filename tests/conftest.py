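import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dualkidney.synthetic_registry import GeneratorConfig, generate_registry

settings.register_profile("repro", database=None, deadline=None, derandomize=True)
settings.load_profile("repro")


def make_records(**columns) -> pd.DataFrame:
    """Small registry frame with sane defaults for unspecified fields."""
    n = max(len(v) for v in columns.values())
    base = {
        "id": np.arange(1, n + 1),
        "group": ["single"] * n,
        "recipient_age": [50.0] * n,
        "recipient_female": [False] * n,
        "race_ethnicity": ["white"] * n,
        "epts": [50.0] * n,
        "dialysis_group": ["1-5y"] * n,
        "pvd": [False] * n,
        "renal_diagnosis": ["diabetes"] * n,
        "bmi": [28.0] * n,
        "cpra": [0.0] * n,
        "donor_age": [40.0] * n,
        "kdri": [1.2] * n,
        "pump": [False] * n,
        "donor_female": [False] * n,
        "cit_hours": [18.0] * n,
        "glomerulosclerosis": ["0-5%"] * n,
        "inotropic_support": [False] * n,
        "sharing": ["local"] * n,
        "distance_miles": [90.0] * n,
        "abo_incompatible": [False] * n,
        "hla_mismatch": [4] * n,
        "induction": ["lymphocyte_depletion"] * n,
        "steroids_maintenance": [True] * n,
        "living_donor": [False] * n,
        "en_bloc": [False] * n,
        "recipient_age_lt18": [False] * n,
        "time_death": [5.0] * n,
        "event_death": [False] * n,
        "time_graftfail": [5.0] * n,
        "event_graftfail": [False] * n,
        "dgf": [False] * n,
        "los_days": [5.0] * n,
        "rejection_6m": [0.0] * n,
        "rejection_1y": [0.0] * n,
        "creatinine_1y": [1.5] * n,
    }
    base.update(columns)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def small_registry() -> pd.DataFrame:
    """Moderate synthetic cohort shared across read-only tests."""
    return generate_registry(GeneratorConfig(n_dual=200, n_single=2000, seed=42))
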