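import numpy as np
import pytest

from telodens import (
    LognormalSmear,
    MigrationCurve,
    default_demo_recipe,
    extract_profile,
    render_gel,
    selections_for,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo():
    """Rendered demo gel with profiles, shared across tests (read-only)."""
    recipe = default_demo_recipe(seed=7)
    img, truth = render_gel(recipe)
    sels = selections_for(recipe)
    profiles = [extract_profile(img, s) for s in sels]
    return {
        "recipe": recipe,
        "image": img,
        "truth": truth,
        "profiles": profiles,
        "markers": [p for p in profiles if p.role == "marker"],
        "lanes": [p for p in profiles if p.role == "sample"],
    }


@pytest.fixture(scope="session")
def migration():
    return MigrationCurve(a=820.0, b=85.0)


@pytest.fixture(scope="session")
def smear():
    return LognormalSmear(3000.0, 0.15)
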