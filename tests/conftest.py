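import numpy as np
import pandas as pd
import pytest

from rvellipsoid.estimators import MEASUREMENT_COLUMNS
from rvellipsoid.synthetic import SyntheticConfig, generate_cohort


def make_measurement_row(dog_id="dog001", group="normal", bw=10.0, session=1,
                         phase="ED", **overrides):
    """One schema-complete measurement row built from exact quarter-ellipsoid
    geometry (r1=2, r2=3, r3=1 by default) so all variants agree."""
    r1, r2, r3 = overrides.pop("r1", 2.0), overrides.pop("r2", 3.0), overrides.pop("r3", 1.0)
    row = {
        "dog_id": dog_id, "group": group, "body_weight_kg": bw,
        "session": session, "phase": phase,
        "csa_rpl_cm2": np.pi * r1 * r2 / 4, "csa_a4c_cm2": np.pi * r1 * r2 / 4,
        "w_rpl_cm": r1, "l_rpl_cm": r2, "w_a4c_cm": r1, "l_a4c_cm": r2,
        "d_a2c_cm": 2 * r3, "d_rps_cm": 2 * r3,
        "v_rt3d_ml": np.pi / 3 * r1 * r2 * r3,
    }
    row.update(overrides)
    return row


@pytest.fixture
def exact_measurements():
    """Three dogs x two phases of noise-free quarter-ellipsoid measurements."""
    rows = []
    for dog, (r1, r2, r3) in [("dog001", (2.0, 3.5, 1.2)), ("dog002", (1.5, 2.8, 0.9)),
                              ("dog003", (2.4, 4.1, 1.5))]:
        rows.append(make_measurement_row(dog, phase="ED", r1=r1, r2=r2, r3=r3))
        rows.append(make_measurement_row(dog, phase="ES", r1=0.8 * r1, r2=0.9 * r2, r3=0.8 * r3))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


@pytest.fixture(scope="session")
def default_cohort():
    """A seeded default-parameter cohort shared across read-only tests."""
    cfg = SyntheticConfig(n_dogs=67, seed=11)
    measurements, truth = generate_cohort(cfg)
    return cfg, measurements, truth
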