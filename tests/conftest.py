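import numpy as np
import pandas as pd
import pytest

from rxtraj import GeneratorConfig, generate, make_worked_fixture


@pytest.fixture(scope="session")
def worked():
    """Hand-authored 10-patient micro-cohort with known answers."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def small_raw():
    """A small generated cohort shared across tests."""
    return generate(GeneratorConfig(n_patients=200, seed=11))


def random_prescriptions(rng: np.random.Generator, n_patients=3, n_drugs=3, n_records=8, span=250):
    """Random small prescription tables for fuzzing against day-grid oracles."""
    drugs = ["sertraline", "quetiapine", "clonazepam", "lamotrigine", "zolpidem"][:n_drugs]
    rows = []
    for p in range(n_patients):
        for _ in range(int(rng.integers(1, n_records + 1))):
            s = int(rng.integers(0, span))
            e = s + int(rng.integers(0, 120))
            rows.append((f"p{p}", drugs[rng.integers(0, len(drugs))], s, e))
    return pd.DataFrame(rows, columns=["patient_id", "drug_name", "start_day", "end_day"])
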