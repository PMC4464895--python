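import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nutgeom import food_composition as fc
from nutgeom import intake_engine as ie
from nutgeom import synthetic_data as sd

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library_frame() -> pd.DataFrame:
    """A small deterministic synthetic food library (raw concentrations)."""
    return sd.gen_food_library(seed=3, n_foods=16)


@pytest.fixture(scope="session")
def derived_library(library_frame) -> pd.DataFrame:
    return fc.derive_frame(library_frame)


@pytest.fixture(scope="session")
def noise_free_study() -> sd.SyntheticStudy:
    return sd.gen_study(sd.StudyConfig(seed=1), noise=False)


@pytest.fixture(scope="session")
def noisy_daily() -> pd.DataFrame:
    """Daily intakes computed through the pipeline for a small noisy study."""
    study = sd.gen_study(sd.StudyConfig(seed=2), noise=True)
    derived = fc.derive_frame(study.foods)
    return ie.compute_daily_intakes(study.bouts, study.rates, study.handling,
                                    derived, study.body_masses)


def random_compositions(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random valid composition rows (mass closure, fiber cascade)."""
    ap = rng.uniform(0, 15, n)
    fat = rng.uniform(0, 20, n)
    ash = rng.uniform(1, 8, n)
    ndf = rng.uniform(20, 55, n)
    total = ap + fat + ash + ndf
    scale = np.where(total > 95, 95 / total, 1.0)
    ap, fat, ash, ndf = ap * scale, fat * scale, ash * scale, ndf * scale
    adf = ndf * rng.uniform(0.5, 0.85, n)
    lignin = adf * rng.uniform(0.2, 0.6, n)
    adicp = rng.uniform(0.2, 2.0, n)
    return pd.DataFrame({
        "food_id": [f"R-{i:03d}" for i in range(n)],
        "species": "sp", "genus": "gen",
        "part_code": rng.choice(["YL", "F", "SD", "BD"], n),
        "cp": ap + adicp, "adicp": adicp, "fat": fat, "ash": ash,
        "ndf": ndf, "adf": adf, "lignin": lignin,
    })
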