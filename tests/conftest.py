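import numpy as np
import pandas as pd
import pytest

from edaphonet.simulate import SimulationConfig, generate_dataset
from edaphonet.tables import AsvTable


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A scaled-down study: 4 sites x 6 samples, 3 modules of 10 ASVs."""
    kw = dict(
        n_sites=4,
        samples_per_site=6,
        n_modules=3,
        asvs_per_module=10,
        n_background_asvs=30,
        n_organelle_decoys=3,
        # tighter coupling than the full-size defaults: with only 24
        # samples the rank-correlation estimates are noisy, so the small
        # study needs stronger within-module signal to stay recoverable
        member_noise_range=(0.7, 1.2),
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_asv_table(rng, n_samples=8, n_asvs=12, max_count=50,
                     domain_split=0.5, kind="raw_counts") -> AsvTable:
    counts = rng.integers(0, max_count + 1, size=(n_samples, n_asvs))
    samples = [f"s{i}" for i in range(n_samples)]
    asvs = [f"a{j}" for j in range(n_asvs)]
    domains = [
        "bacteria" if j < n_asvs * domain_split else "eukaryote"
        for j in range(n_asvs)
    ]
    df = pd.DataFrame(counts, index=samples, columns=asvs)
    if kind == "relative":
        lib = df.sum(axis=1).replace(0, 1)
        df = df.div(lib, axis=0)
    return AsvTable(df.astype(float) if kind != "raw_counts" else df,
                    pd.Series(domains, index=asvs), kind)
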