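import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from consrank.contacts import ContactMap
from consrank.model_io import Model
from consrank.synth import SyntheticSpec, generate_ensemble, make_reference_dimer, target_spec

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

warnings.filterwarnings("ignore", message=".*end_gap_score.*")


def make_maps(contact_sets: dict[str, set]) -> list[ContactMap]:
    return [ContactMap(mid, frozenset(cs)) for mid, cs in contact_sets.items()]


def contact(i: int, j: int):
    return (("A", i), ("B", j))


def random_maps(rng: np.random.Generator, n: int, universe: int = 60,
                lo: int = 3, hi: int = 20) -> list[ContactMap]:
    """Random contact maps over a shared universe of possible contacts."""
    pool = [contact(i, j) for i in range(1, 11) for j in range(1, universe // 10 + 1)]
    maps = []
    for k in range(n):
        m = rng.integers(lo, hi + 1)
        picks = rng.choice(len(pool), size=min(m, len(pool)), replace=False)
        maps.append(ContactMap(f"m{k:03d}", frozenset(pool[p] for p in picks)))
    return maps


@pytest.fixture(scope="session")
def micro_maps():
    """The three-model worked example: {a,b}, {a,c}, {a}."""
    a, b, c = contact(1, 1), contact(2, 2), contact(3, 3)
    return make_maps({"M1": {a, b}, "M2": {a, c}, "M3": {a}})


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def reference_dimer(default_spec):
    return make_reference_dimer(default_spec)


@pytest.fixture(scope="session")
def small_ensemble():
    """A small mixed ensemble plus ground truth and target (seeded)."""
    spec = SyntheticSpec(n_models=30, planted_fraction=0.4, seed=42)
    models, truth = generate_ensemble(spec)
    return spec, models, truth, target_spec(spec)


def assert_valid_model(model: Model):
    assert len(model.chains) >= 2
    coords = model.arrays()["coords"]
    assert np.isfinite(coords).all()
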