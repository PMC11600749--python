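"""Study-shaped synthetic datasets with planted, recoverable signal.

The generator emulates the structure of a field-sampled soil amplicon
study: samples clustered three-per-field across two states, a sparse
Genus-level count table with heavy per-sample depth variation, soil
chemistry and microbial-density covariates, four disease severities with a
point mass at zero, and two yields whose means differ by potato variety.

Counts follow a logistic-normal-multinomial model: per-sample latent
log-abundances (taxon baseline + field/state random intercepts + a class
effect on designated signal taxa + Gaussian noise) are softmax-transformed
and drawn as a multinomial at a depth sampled uniformly from
``depth_range``.  Structural zeros are then planted to hit the target
sparsity.  A per-field latent binary condition both shifts the signal taxa
(by ``effect_size`` on the log scale) and raises the disease-positive
rate, so the planted taxa are genuinely predictive of the labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from microfms.io_types import (
    RANKS,
    OTUTable,
    TaxonomyMap,
    read_otu_table,
    read_sample_table,
    read_taxonomy,
    write_otu_table,
    write_sample_table,
    write_taxonomy,
)

DISEASE_RESPONSES: tuple[str, ...] = ("Scab", "Scabpit", "Scabsuper", "Black_Scurf")
YIELD_RESPONSES: tuple[str, ...] = ("Yield_Meter", "Yield_Plant")
RESPONSES: tuple[str, ...] = YIELD_RESPONSES + DISEASE_RESPONSES

#: Binarized positive rates the disease models are anchored to, matching
#: the prevalences of the study population being emulated (scab ~74%,
#: pitted scab ~43%, superficial scab ~63%, black scurf ~9.5%).
DISEASE_BASE_RATES: dict[str, float] = {
    "Scab": 0.74,
    "Scabpit": 0.43,
    "Scabsuper": 0.63,
    "Black_Scurf": 0.095,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the study-scale dataset.

    ``sparsity`` is the target fraction of zero cells (structural zeros are
    planted on top of sampling zeros to reach it); ``effect_size`` is the
    log-scale abundance shift of signal taxa between the two latent
    classes; ``noise_sd`` the per-cell log-abundance noise.  ``field_sd``
    and ``state_sd`` are placeholder variance components for the
    field-clustered sampling (no field-level variance is published for the
    emulated study, so they are exposed here).
    """

    n_fields: int = 85
    samples_per_field: int = 3
    n_taxa_genus: int = 485
    n_varieties: int = 6
    depth_range: tuple[int, int] = (5_000, 50_000)
    sparsity: float = 0.7
    n_signal_taxa: int = 5
    effect_size: float = 1.5
    env_dim: int = 12
    noise_sd: float = 1.0
    seed: int = 0
    field_sd: float = 0.3
    state_sd: float = 0.2
    missing_rate: float = 0.1
    black_scurf_rate: float = DISEASE_BASE_RATES["Black_Scurf"]

    def __post_init__(self) -> None:
        for name in ("n_fields", "samples_per_field", "n_taxa_genus", "n_varieties"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sparsity < 1:
            raise ValueError("sparsity must be in (0, 1)")
        if self.n_signal_taxa >= self.n_taxa_genus:
            raise ValueError("n_signal_taxa must be < n_taxa_genus")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("depth_range must be an increasing pair of depths >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.env_dim < 3:
            raise ValueError("env_dim must be >= 3 (soil block + density block)")

    def imbalanced_preset(self) -> "SyntheticConfig":
        """Black-scurf-like extreme imbalance (~2.5% positive class)."""
        return replace(self, black_scurf_rate=0.025)


@dataclass
class SyntheticDataset:
    """A complete generated study: counts, lineage, covariates, truth."""

    counts: OTUTable
    taxonomy: TaxonomyMap
    metadata: pd.DataFrame
    env: pd.DataFrame
    responses: pd.DataFrame
    truth: dict[str, list[str]]
    #: per-sample latent binary condition, one column per response
    latent_class: pd.DataFrame
    config: SyntheticConfig

    @property
    def soil(self) -> pd.DataFrame:
        """Soil-chemistry block of the environmental matrix."""
        return self.env[[c for c in self.env.columns if c.startswith("soil_")]]

    @property
    def density(self) -> pd.DataFrame:
        """Microbial population-density block of the environmental matrix."""
        return self.env[[c for c in self.env.columns if c.startswith("density_")]]


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _make_taxonomy(rng: np.random.Generator, n_genus: int) -> TaxonomyMap:
    """Random but consistent 5-rank lineage (one parent per child)."""
    sizes = {
        "Family": max(2, n_genus // 3),
        "Order": max(2, n_genus // 6),
        "Class": max(2, n_genus // 10),
        "Phylum": max(2, n_genus // 16),
    }
    genus_ids = [f"g{i:04d}" for i in range(n_genus)]
    fam_of_genus = rng.integers(sizes["Family"], size=n_genus)
    ord_of_fam = rng.integers(sizes["Order"], size=sizes["Family"])
    cls_of_ord = rng.integers(sizes["Class"], size=sizes["Order"])
    phy_of_cls = rng.integers(sizes["Phylum"], size=sizes["Class"])
    fam = fam_of_genus
    order = ord_of_fam[fam]
    cls = cls_of_ord[order]
    phy = phy_of_cls[cls]
    lineage = pd.DataFrame(
        {
            "Phylum": [f"P{p:02d}" for p in phy],
            "Class": [f"C{c:03d}" for c in cls],
            "Order": [f"O{o:03d}" for o in order],
            "Family": [f"F{f:03d}" for f in fam],
            "Genus": genus_ids,
        },
        index=pd.Index(genus_ids, name="taxon_id"),
    )
    return TaxonomyMap(lineage)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete dataset; identical (config, seed) -> identical data.

    Raises if the target sparsity is below what multinomial sampling alone
    already produces at the configured depths (structural zeros can only
    add sparsity, never remove it).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fields * config.samples_per_field
    p = config.n_taxa_genus

    taxonomy = _make_taxonomy(rng, p)
    genus_ids = taxonomy.lineage.index

    # --- metadata: fields, states, varieties, per-field latent condition
    field_ids = [f"F{f:03d}" for f in range(config.n_fields)]
    n_mn = max(1, int(round(0.35 * config.n_fields)))
    field_state = ["MN"] * n_mn + ["WI"] * (config.n_fields - n_mn)
    field_variety = rng.integers(config.n_varieties, size=config.n_fields)
    # one latent binary condition per response, constant within a field
    field_class = rng.integers(2, size=(config.n_fields, len(RESPONSES)))

    sample_ids = pd.Index(
        [f"S{k:04d}" for k in range(n)], name="sample_id"
    )
    sample_field = np.repeat(np.arange(config.n_fields), config.samples_per_field)
    metadata = pd.DataFrame(
        {
            "field_id": [field_ids[f] for f in sample_field],
            "state": [field_state[f] for f in sample_field],
            "variety": [f"variety_{field_variety[f]}" for f in sample_field],
        },
        index=sample_ids,
    )
    latent = pd.DataFrame(
        field_class[sample_field], index=sample_ids, columns=list(RESPONSES)
    )

    # --- planted signal taxa: disjoint blocks, one per response
    perm = rng.permutation(p)
    truth: dict[str, list[str]] = {}
    for i, resp in enumerate(RESPONSES):
        lo = i * config.n_signal_taxa
        hi = lo + config.n_signal_taxa
        if hi > p:  # not enough taxa for disjoint blocks: recycle
            block = perm[np.arange(lo, hi) % p]
        else:
            block = perm[lo:hi]
        truth[resp] = sorted(genus_ids[block])

    # each response's latent condition shifts that response's block only
    class_shift = np.zeros((n, p))
    for resp in RESPONSES:
        cols = genus_ids.get_indexer(truth[resp])
        class_shift[:, cols] += (
            config.effect_size * latent[resp].to_numpy()[:, None]
        )

    # --- latent log-abundances
    baseline = rng.normal(0.0, 1.5, size=p)
    field_intercept = rng.normal(0.0, config.field_sd, size=(config.n_fields, p))
    state_effect = rng.normal(0.0, config.state_sd, size=(2, p))
    state_idx = (np.asarray(field_state)[sample_field] == "WI").astype(int)
    eta = (
        baseline[None, :]
        + field_intercept[sample_field]
        + state_effect[state_idx]
        + class_shift
        + rng.normal(0.0, config.noise_sd, size=(n, p))
    )
    props = np.exp(eta - eta.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)

    # --- counts with planted structural zeros
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)
    counts = np.empty((n, p), dtype=np.int64)
    for k in range(n):
        counts[k] = rng.multinomial(depths[k], props[k])
    z0 = float((counts == 0).mean())
    if z0 > config.sparsity + 0.05:
        raise ValueError(
            f"sparsity target {config.sparsity} unreachable: multinomial "
            f"sampling alone already leaves {z0:.3f} of cells zero at the "
            "configured depths; raise the target or lower the depths"
        )
    if z0 < config.sparsity:
        mask_rate = (config.sparsity - z0) / (1.0 - z0)
        struct = rng.random((n, p)) < mask_rate
        struct[np.arange(n), props.argmax(axis=1)] = False  # keep rows non-empty
        masked = np.where(struct, 0.0, props)
        masked /= masked.sum(axis=1, keepdims=True)
        for k in range(n):
            counts[k] = rng.multinomial(depths[k], masked[k])
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=genus_ids)
    otu = OTUTable(counts_df, rank="Genus")

    # --- environment: field-structured soil block + density block
    n_soil = config.env_dim - 2
    field_env = rng.normal(0.0, 1.0, size=(config.n_fields, config.env_dim))
    env = field_env[sample_field] + rng.normal(0.0, 0.5, size=(n, config.env_dim))
    env_cols = [f"soil_{j}" for j in range(n_soil)] + ["density_bacteria", "density_fungi"]
    env_df = pd.DataFrame(env, index=sample_ids, columns=env_cols)

    # --- responses
    # The latent field condition mediates the microbiome-disease link: it
    # raises both the signal-taxon abundance (by effect_size) and the
    # disease-positive rate, so the class-conditional expected relative
    # abundance of a response's signal taxa increases with its positive
    # rate.  At effect_size = 0 the condition leaves abundances untouched
    # and the microbiome carries no disease signal — an exact null.
    rel = counts / counts.sum(axis=1, keepdims=True)
    env0 = _zscore(env[:, 0])
    responses = pd.DataFrame(index=sample_ids, columns=list(RESPONSES), dtype=float)
    for resp in DISEASE_RESPONSES:
        rate = (
            config.black_scurf_rate
            if resp == "Black_Scurf"
            else DISEASE_BASE_RATES[resp]
        )
        class_term = (
            _zscore(latent[resp].to_numpy())
            if config.effect_size > 0
            else np.zeros(n)
        )
        lin = _logit(rate) + 1.5 * class_term + 0.8 * env0
        positive = rng.random(n) < 1.0 / (1.0 + np.exp(-lin))
        if resp == "Black_Scurf":  # percentage coverage
            severity = np.where(positive, 100.0 * rng.beta(2.0, 5.0, size=n), 0.0)
        else:  # tuber counts
            severity = np.where(positive, 1.0 + rng.poisson(3.0, size=n), 0.0)
        responses[resp] = severity

    variety_mean = {
        "Yield_Meter": rng.normal(2500.0, 400.0, size=config.n_varieties),
        "Yield_Plant": rng.normal(1200.0, 250.0, size=config.n_varieties),
    }
    env_coef = rng.normal(0.0, 40.0, size=config.env_dim)
    for resp in YIELD_RESPONSES:
        sig = genus_ids.get_indexer(truth[resp])
        abund = _zscore(rel[:, sig].mean(axis=1))
        values = (
            variety_mean[resp][field_variety[sample_field]]
            + env @ env_coef
            + 30.0 * abund
            + rng.normal(0.0, 150.0, size=n)
        )
        responses[resp] = np.clip(values, 1.0, None)

    if config.missing_rate > 0:
        for resp in RESPONSES:
            drop = rng.random(n) < config.missing_rate
            responses.loc[drop, resp] = np.nan

    return SyntheticDataset(
        counts=otu,
        taxonomy=taxonomy,
        metadata=metadata,
        env=env_df,
        responses=responses,
        truth=truth,
        latent_class=latent,
        config=config,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def aggregate_truth(dataset: SyntheticDataset, level: str) -> list[str]:
    """Signal taxa at a coarser rank, pooled over all responses.

    A rank-``level`` taxon is signal iff at least one of its descendant
    genera is signal for some response.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    signal_genera = sorted({g for taxa in dataset.truth.values() for g in taxa})
    names = dataset.taxonomy.names_at(signal_genera, level)
    return sorted(set(names))


def truth_at_level(dataset: SyntheticDataset, response: str, level: str) -> list[str]:
    """Signal taxa of one response lifted to a coarser rank."""
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    names = dataset.taxonomy.names_at(dataset.truth[response], level)
    return sorted(set(names))


# ---------------------------------------------------------------------------
# on-disk format


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write counts (taxa rows x sample columns TSV), taxonomy, CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_otu_table(dataset.counts, out / "counts.tsv")
    write_taxonomy(dataset.taxonomy, out / "taxonomy.tsv")
    write_sample_table(dataset.metadata, out / "metadata.csv")
    write_sample_table(dataset.env, out / "env.csv")
    write_sample_table(dataset.responses, out / "responses.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)


def read_dataset(in_dir: str | Path) -> dict:
    """Read a written dataset back as a dict of components."""
    path = Path(in_dir)
    with open(path / "truth.json") as fh:
        truth = json.load(fh)
    return {
        "counts": read_otu_table(path / "counts.tsv", orientation="taxa_rows"),
        "taxonomy": read_taxonomy(path / "taxonomy.tsv"),
        "metadata": read_sample_table(path / "metadata.csv"),
        "env": read_sample_table(path / "env.csv"),
        "responses": read_sample_table(path / "responses.csv"),
        "truth": truth,
    }
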