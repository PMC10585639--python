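import numpy as np
import pytest

from octnorms import Cohort, EtdrsGrid, EyeRecord, default_config, generate
from octnorms.io import SECTORS


def make_grid(base: float = 300.0, **overrides) -> EtdrsGrid:
    values = {
        "center_fovea": base - 40,
        "parafovea_superior": base + 20,
        "parafovea_nasal": base + 25,
        "parafovea_inferior": base + 18,
        "parafovea_temporal": base + 12,
        "perifovea_superior": base - 18,
        "perifovea_nasal": base - 4,
        "perifovea_inferior": base - 28,
        "perifovea_temporal": base - 32,
    }
    values.update(overrides)
    return EtdrsGrid(**values)


def make_record(subject_id="S1", ethnicity="European", age=60.0, sex="female",
                eye="OD", base=300.0, choroid=280.0, **grid_overrides) -> EyeRecord:
    return EyeRecord(
        subject_id=subject_id, ethnicity=ethnicity, age=age, sex=sex, eye=eye,
        grid=make_grid(base, **grid_overrides), choroid=choroid,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (42 Ghanaian + 37 European)."""
    cohort, _ = generate(default_config(seed=20240917))
    return cohort


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for Monte Carlo convergence checks (2000 per group)."""
    config = default_config(seed=55)
    from dataclasses import replace

    config = replace(config, n_ghanaian=2000, n_european=2000,
                     eye_missing_prob_ghanaian=0.0)
    cohort, truth = generate(config)
    return cohort, truth, config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
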