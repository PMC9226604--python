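import numpy as np
import pandas as pd
import pytest

from mycolink import (
    OtuTable,
    SimulationConfig,
    build_networks_by_group,
    compute_responses,
    filter_low_depth_samples,
    filter_rare_otus,
    rarefy_once,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def experiment():
    """One default simulated experiment shared across the suite."""
    config = SimulationConfig(rng_seed=1)
    soil, root, traits, truth = simulate_experiment(config)
    return {
        "config": config,
        "soil": soil,
        "root": root,
        "traits": traits,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def rarefied_root(experiment):
    """Filtered + rarefied root table, the input to network inference."""
    table, discarded = filter_low_depth_samples(experiment["root"], 5000)
    table = filter_rare_otus(table, 10)
    return rarefy_once(table, 5283, seed=11), discarded


@pytest.fixture(scope="session")
def networks(rarefied_root):
    table, _ = rarefied_root
    return build_networks_by_group(table)


@pytest.fixture(scope="session")
def responses(experiment):
    return compute_responses(experiment["traits"])


@pytest.fixture
def toy_table():
    """Tiny hand-checkable OTU table: 3 samples x 5 OTUs."""
    counts = pd.DataFrame(
        [[0, 3, 4, 5, 60], [3, 3, 3, 3, 20], [0, 3, 3, 3, 20]],
        index=["s1", "s2", "s3"],
        columns=[f"o{i}" for i in range(1, 6)],
    )
    meta = pd.DataFrame(
        {
            "host": ["A", "B", "A"],
            "inoculum": ["A", "A", "B"],
            "compartment": ["root"] * 3,
        },
        index=counts.index,
    )
    return OtuTable(counts, meta)


def balanced_traits(effects=None, noise=0.0, reps=3, seed=0):
    """Small factorial trait table with known multiplicative effects."""
    rng = np.random.default_rng(seed)
    hosts = ["A", "B"]
    inocula = ["A", "B", "control"]
    effects = effects or {}
    rows = []
    for h in hosts:
        for i in inocula:
            for r in range(1, reps + 1):
                total = 1.0 * effects.get((h, i), 1.0)
                if noise:
                    total *= float(np.exp(rng.normal(0, noise)))
                rows.append(
                    {
                        "pot_id": f"pot_{h}_{i}_{r}",
                        "host": h,
                        "inoculum": i,
                        "aboveground_biomass": 0.6 * total,
                        "belowground_biomass": 0.4 * total,
                        "total_biomass": total,
                        "height": 10.0,
                        "colonization": 0.5,
                        "n_survivors": 3,
                    }
                )
    return pd.DataFrame(rows)
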