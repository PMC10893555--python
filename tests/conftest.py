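import numpy as np
import pytest

import signalniche as sn


@pytest.fixture(scope="session")
def demo_community():
    """Seeded 30-species synthetic community with fitted signal space."""
    profiles = sn.default_community(seed=0)
    traits = sn.simulate_traits(profiles, seed=1)
    means = sn.per_male_means(traits)
    space = sn.build_signal_space(means)
    niches = sn.build_niches(space)
    return {
        "profiles": profiles,
        "traits": traits,
        "means": means,
        "space": space,
        "niches": niches,
        "statuses": {p.code: p.status for p in profiles},
    }


@pytest.fixture(scope="session")
def demo_overlap_tables(demo_community):
    return sn.overlap_table(demo_community["niches"])


@pytest.fixture(scope="session")
def demo_snapshots(demo_community):
    profiles = demo_community["profiles"]
    checklists = sn.simulate_checklists(
        profiles, n_per_day=30, day_range=(92, 167), seed=2, violation_fraction=0.05
    )
    filtered, _ = sn.filter_checklists(checklists)
    occ = sn.occurrence_matrix(filtered, species=[p.code for p in profiles])
    window_means, windows = sn.window_average(occ)
    snaps = sn.reconstruct_communities(
        window_means, windows, demo_community["statuses"]
    )
    return {"checklists": checklists, "filtered": filtered, "occ": occ,
            "window_means": window_means, "windows": windows, "snapshots": snaps}


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
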