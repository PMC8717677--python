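import numpy as np
import pandas as pd
import pytest

from drugspectrum import (
    CohortConfig,
    default_attribute_table,
    default_gen_specs,
    generate_cohort_with_truth,
    label_cohort,
    normalize_cohort,
)
from drugspectrum.cohort import COHORT_COLUMNS


@pytest.fixture(scope="session")
def attr_table():
    return default_attribute_table()


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-size synthetic cohort with its generation truth."""
    config = CohortConfig(
        n_patients=400,
        success_fraction=0.5,
        attribute_specs=default_gen_specs(),
        bp_noise_sd=5.0,
        seed=11,
    )
    return generate_cohort_with_truth(config)


@pytest.fixture(scope="session")
def normalized(sim_cohort):
    df, _ = sim_cohort
    return normalize_cohort(label_cohort(df))


def make_row(pid="P1", attr_value=None, monotherapy=True, on_label=True,
             sbp=125.0, dbp=80.0, **overrides):
    """One schema-complete cohort row with plausible in-range values."""
    table = default_attribute_table()
    row = {"patient_id": pid}
    for name, spec in table.items():
        mid = (spec.attr_min + spec.attr_max) / 2
        row[name] = attr_value if attr_value is not None else mid
    row["Sex"] = 1.0
    row["monotherapy"] = monotherapy
    row["on_label_dose"] = on_label
    for d in range(1, 6):
        row[f"sbp_d{d}"] = sbp
        row[f"dbp_d{d}"] = dbp
    row.update(overrides)
    return row


def make_cohort(rows):
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


@pytest.fixture
def tiny_cohort():
    return make_cohort([make_row(f"P{i}") for i in range(3)])
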