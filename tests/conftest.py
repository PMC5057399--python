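import numpy as np
import pytest

from adlcat import ItemBank, ItemParameters, ModelFamily, fixture_bank


@pytest.fixture(scope="session")
def cadl() -> ItemBank:
    return fixture_bank("CADL")


@pytest.fixture(scope="session")
def adl_male() -> ItemBank:
    return fixture_bank("ADL-male")


@pytest.fixture(scope="session")
def adl_female() -> ItemBank:
    return fixture_bank("ADL-female")


def dichotomous(delta: float, item_id: str = "") -> ItemParameters:
    """Convenience Rasch item with difficulty ``delta``."""
    return ItemParameters(
        item_id=item_id or f"delta={delta:g}",
        model=ModelFamily.RASCH_DICHOTOMOUS,
        discrimination=1.0,
        step_difficulties=(delta,),
    )


def random_gpcm(rng: np.random.Generator, item_id: str = "g") -> ItemParameters:
    """Random polytomous item with 1-3 steps, parameters in realistic ranges."""
    m = int(rng.integers(1, 4))
    return ItemParameters(
        item_id=item_id,
        model=ModelFamily.GPCM,
        discrimination=float(rng.uniform(0.4, 3.5)),
        step_difficulties=tuple(np.sort(rng.uniform(-3, 3, size=m))),
    )
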