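import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import quitcea as qc
from quitcea.params_io import DISEASES, GENDERS, EpiTables, epi_columns

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_epi() -> EpiTables:
    """The packaged UK-like synthetic tables."""
    return qc.generate_default()


@pytest.fixture(scope="session")
def base_inputs(default_epi) -> qc.ModelInputs:
    """Base-case parameters on the default synthetic tables."""
    return qc.load_base_case(default_epi)


@pytest.fixture(scope="session")
def base_arms(base_inputs) -> tuple[qc.Outcomes, qc.Outcomes]:
    """Weighted (intervention, control) outcomes at base case."""
    return (
        qc.run_weighted(base_inputs, qc.Arm.INTERVENTION),
        qc.run_weighted(base_inputs, qc.Arm.CONTROL),
    )


def flat_epi_frame(
    ages,
    m_gen=0.01,
    p=(0.2, 0.3, 0.5),
    prev=1e-3,
    rr_death=(2.0, 1.3),
    rr_disease=(2.0, 1.3),
) -> pd.DataFrame:
    """A constant-rate table over the given ages, both genders."""
    rows = []
    for age in ages:
        for gender in GENDERS:
            row = {
                "age": age,
                "gender": gender,
                "m_gen": m_gen,
                "p_smoker": p[0],
                "p_former": p[1],
                "p_never": p[2],
                "rr_death_smoker": rr_death[0],
                "rr_death_former": rr_death[1],
            }
            for d in DISEASES:
                row[f"prev_{d}"] = prev
                row[f"rr_{d}_smoker"] = rr_disease[0]
                row[f"rr_{d}_former"] = rr_disease[1]
            rows.append(row)
    return pd.DataFrame(rows)[epi_columns()]


def make_epi(frame: pd.DataFrame) -> EpiTables:
    epi = EpiTables(frame.set_index(["age", "gender"]).sort_index())
    epi.validate()
    return epi


@pytest.fixture
def toy_epi() -> EpiTables:
    """A tiny 2-age x 2-gender table."""
    return make_epi(flat_epi_frame([30, 31]))


def base_config() -> dict:
    """The packaged base-case configuration as a dict (editable in tests)."""
    import tomllib

    with open(qc.default_config_path(), "rb") as fh:
        return tomllib.load(fh)
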