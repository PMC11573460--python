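import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_pool():
    from forageselect.synthetic import generate_species_pool

    return generate_species_pool(n_species=12, seed=11)


@pytest.fixture(scope="session")
def trial_design():
    from forageselect.synthetic import TrialDesign

    return TrialDesign()


@pytest.fixture
def tiny_quadrats():
    """Two plots x one period, three species in two food items."""
    rows = []
    for plot in ("A", "B"):
        for q in range(1, 4):
            for sp, bm in (("g1", 6.0), ("g2", 3.0), ("f1", 1.0)):
                rows.append(
                    {
                        "plot": plot,
                        "period": 1,
                        "quadrat": f"q{q}",
                        "species_id": sp,
                        "biomass": bm,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_family_map():
    return {"g1": "Poaceae", "g2": "Poaceae", "f1": "forbs"}


@pytest.fixture
def tiny_nutrients():
    return pd.DataFrame(
        {"cp": [10.0, 12.0, 18.0], "ndf": [60.0, 62.0, 40.0], "adf": [34.0, 33.0, 25.0]},
        index=["g1", "g2", "f1"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
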