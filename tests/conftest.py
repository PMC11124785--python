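import dataclasses

import numpy as np
import pandas as pd
import pytest

from clopk.estimate import DEFAULT_ESTIMATES, FIXED_DEFAULTS
from clopk.simulate import (
    StudyDesign,
    VariabilityModel,
    apply_lloq,
    generate_dataset,
    study_design,
)


@pytest.fixture(scope="session")
def known_values() -> dict:
    """Flat name→value map at the package default population parameters."""
    return dict(DEFAULT_ESTIMATES, **FIXED_DEFAULTS)


@pytest.fixture(scope="session")
def zero_var() -> VariabilityModel:
    return VariabilityModel(
        iiv_V_cP=0.0, iiv_V_c_iaM=0.0, iiv_FR1=0.0, iiv_F=0.0,
        iov_F=0.0, iov_MTT=0.0, sigma_prop=0.0,
    )


def small_design(study: int, n_subjects: int) -> StudyDesign:
    return dataclasses.replace(study_design(study), n_subjects=n_subjects)


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    """Two-study dataset with 4 subjects per study, LLOQ-excluded."""
    ds = generate_dataset([small_design(1, 4), small_design(2, 4)], seed=202)
    return apply_lloq(ds)


@pytest.fixture(scope="session")
def zero_noise_dataset(zero_var) -> pd.DataFrame:
    """Noise- and variability-free dataset (3 subjects per study)."""
    ds = generate_dataset(
        [small_design(1, 3), small_design(2, 3)],
        vars_=[zero_var, zero_var], seed=77,
    )
    return apply_lloq(ds)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
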