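import numpy as np
import pandas as pd
import pytest

from microfms.io_types import OTUTable, TaxonomyMap
from microfms.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_table() -> OTUTable:
    """4 samples x 5 taxa with zeros, unequal depths."""
    data = pd.DataFrame(
        [
            [5, 0, 3, 0, 2],
            [0, 4, 0, 1, 5],
            [2, 2, 2, 2, 2],
            [10, 0, 0, 0, 0],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["t1", "t2", "t3", "t4", "t5"],
        dtype=float,
    )
    return OTUTable(data, rank="Genus")


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    lineage = pd.DataFrame(
        {
            "Phylum": ["P1", "P1", "P2", "P2", None],
            "Class": ["C1", "C1", "C2", "C3", None],
            "Order": ["O1", "O2", "O3", "O4", None],
            "Family": ["F1", "F2", "F3", "F4", None],
            "Genus": ["t1", "t2", "t3", "t4", "t5"],
        },
        index=pd.Index(["t1", "t2", "t3", "t4", "t5"], name="taxon_id"),
    )
    return TaxonomyMap(lineage)


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A quick-to-generate study-shaped configuration for unit tests."""
    defaults = dict(
        n_fields=20,
        samples_per_field=3,
        n_taxa_genus=40,
        n_varieties=3,
        depth_range=(1_000, 5_000),
        sparsity=0.5,
        n_signal_taxa=3,
        effect_size=1.5,
        env_dim=5,
        noise_sd=1.0,
        missing_rate=0.1,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(
        SyntheticConfig(
            n_fields=20,
            samples_per_field=3,
            n_taxa_genus=40,
            n_varieties=3,
            depth_range=(1_000, 5_000),
            sparsity=0.5,
            n_signal_taxa=3,
            effect_size=1.5,
            env_dim=5,
            noise_sd=1.0,
            missing_rate=0.1,
            seed=7,
        )
    )


def random_count_table(rng: np.random.Generator, n=12, p=8, zero_frac=0.4) -> OTUTable:
    counts = rng.integers(1, 200, size=(n, p)).astype(float)
    mask = rng.random((n, p)) < zero_frac
    # keep one positive entry per row so compositions stay defined
    mask[np.arange(n), rng.integers(p, size=n)] = False
    counts[mask] = 0.0
    return OTUTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n)],
            columns=[f"t{j}" for j in range(p)],
        )
    )
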