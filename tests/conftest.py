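import pytest

from mirversions.mirbase_io import build_database
from mirversions.synthetic_release import HistoryConfig, demo_history, generate_history


def make_history(seed: int, **overrides):
    """One seeded study-condition history: <=5 versions, small populations,
    rename pressure high enough to make versions distinguishable."""
    config = dict(
        n_versions=3 + seed % 3,
        n_initial_precursors=15 + 5 * (seed % 4),
        rename_rate=0.30,
        seed=seed,
    )
    config.update(overrides)
    return generate_history(HistoryConfig(**config))


@pytest.fixture(scope="session")
def demo_releases():
    return demo_history()


@pytest.fixture(scope="session")
def demo_db(demo_releases):
    return build_database(demo_releases)


@pytest.fixture(scope="session")
def histories():
    """Twenty seeded histories with their event logs and compiled databases."""
    out = []
    for seed in range(20):
        releases, events = make_history(seed)
        out.append((releases, events, build_database(releases)))
    return out
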