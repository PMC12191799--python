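import numpy as np
import pandas as pd
import pytest

import ratiosurv as rs


@pytest.fixture(scope="session")
def small_cohort():
    """Small all-null synthetic cohort shared by read-only tests."""
    cfg = rs.SimulationConfig(n_subjects=80, n_features=60, seed=11)
    expr = rs.generate_expression(cfg)
    cohort = rs.generate_survival(cfg, expr)
    return cfg, expr, cohort


@pytest.fixture(scope="session")
def small_screen(small_cohort):
    cfg, expr, cohort = small_cohort
    est = rs.RatioSurvivalScreen(anchor=cfg.anchor_feature_id)
    est.fit(rs.log2p4_transform(expr), cohort)
    return est


@pytest.fixture
def toy_cohort_frame():
    """Hand-built clinical table: 8 subjects, mixed stages and day values."""
    return pd.DataFrame(
        {
            "subject_id": [f"P{i}" for i in range(8)],
            "days_to_death": [0, 1, 100, 3649, 3650, 500, 700, 900],
            "event": [True] * 8,
            "stage": ["IIIC", "IIIC", "IIIC", "IIIC", "IIIC", "IV", "IIIC", "IIIC"],
        }
    )


def make_expression(values: np.ndarray, feature_ids, subject_ids, state="normalized"):
    return rs.ExpressionMatrix(
        pd.DataFrame(values, index=list(feature_ids), columns=list(subject_ids)),
        transform_state=state,
    )
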