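import numpy as np
import pandas as pd
import pytest

from methdrift.cohort import CohortSimSpec, generate_cohort
from methdrift.core_io import BetaMatrix, SampleSheet


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully structured cohort used across test modules."""
    spec = CohortSimSpec(
        seed=11,
        n_probes=800,
        n_nonuser_gain=60,
        delta_beta_gain=0.10,
        n_user_loss=60,
        delta_beta_loss=0.10,
        n_clock_cpgs=30,
    )
    return generate_cohort(spec)


@pytest.fixture
def tiny_beta():
    rng = np.random.default_rng(0)
    values = rng.random((6, 4))
    return BetaMatrix(
        [f"cg{i}" for i in range(6)], [f"s{j}" for j in range(4)], values
    )


def paired_sheet(n_subjects=6, n_users=3, location="proximal", seed=0):
    """Minimal single-location paired sheet: n subjects x 2 timepoints."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        subj = f"S{i:02d}"
        user = i < n_users
        age = 50.0 + i
        for tp in ("t1", "t2"):
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "subject_id": subj,
                    "timepoint": tp,
                    "location": location,
                    "aspirin": "long_term_user" if user else "nonuser",
                    "switched_at_t2": False,
                    "age": age + (10.0 if tp == "t2" else 0.0),
                    "bmi": float(rng.normal(25, 2)),
                    "polyps": bool(rng.random() < 0.3),
                    "batch": f"chip{rng.integers(1, 3)}",
                }
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def sheet6():
    return paired_sheet()
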