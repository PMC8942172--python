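import numpy as np
import pandas as pd
import pytest

from occaban import (
    DesignConfig,
    GenerativeHyper,
    HABITAT_TYPES,
    HabitatMatrix,
    SurveyTable,
    build_design,
    generate_habitats,
    generate_survey,
    generate_truth,
)


@pytest.fixture(scope="session")
def tiny_config():
    return DesignConfig(
        n_regions=4,
        n_species=6,
        settlements_per_region=(2, 3),
        plots_per_settlement=(4, 6),
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_config):
    return generate_truth(tiny_config, GenerativeHyper(rho=0.3), seed=101)


@pytest.fixture(scope="session")
def tiny_table(tiny_config, tiny_truth):
    return generate_survey(tiny_config, tiny_truth, seed=102)


@pytest.fixture(scope="session")
def tiny_design(tiny_table):
    return build_design(tiny_table)


@pytest.fixture(scope="session")
def tiny_habitat(tiny_config):
    return generate_habitats(tiny_config.n_species, seed=103)


@pytest.fixture
def toy_survey_frame():
    """Hand-written two-settlement survey: 1 abandoned + 1 inhabited."""
    return pd.DataFrame(
        {
            "plot_id": ["p1", "p2", "p3", "p4"],
            "region_id": ["r1", "r1", "r1", "r1"],
            "settlement_id": ["s1", "s1", "s2", "s2"],
            "land_use": ["paddy", "dry_field", "built_up", "paddy"],
            "abandoned": [1, 1, 0, 0],
            "years_since_abandonment": [12, 12, 0, 0],
            "mat": [10.0, 10.0, 11.0, 11.0],
            "month": [6, 6, 7, 7],
        }
    )


def make_table(frame: pd.DataFrame, occupancy: np.ndarray,
               species=None) -> SurveyTable:
    species = species or [f"sp{i}" for i in range(occupancy.shape[0])]
    occ = pd.DataFrame(
        occupancy, index=species, columns=frame["plot_id"]
    )
    return SurveyTable(plots=frame, occupancy=occ)


@pytest.fixture
def uniform_habitat():
    """Deterministic 6-species habitat matrix covering several types."""
    H = np.zeros((6, 11), dtype=int)
    H[:, 3] = [1, 1, 1, 0, 0, 0]   # grassland for first half
    H[:, 0] = [0, 0, 0, 1, 1, 1]   # forest for second half
    H[:, 4] = [1, 0, 1, 0, 1, 0]   # crop_field mixed
    species = [f"sp{i:03d}" for i in range(6)]
    return HabitatMatrix(
        H=pd.DataFrame(H, index=species, columns=HABITAT_TYPES),
        red_list=pd.Series([1, 0, 0, 1, 0, 0], index=species),
    )
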