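"""Zero replacement, normalization, scaling, binarization, and splitting.

Compositional count tables only carry relative information, and log-ratio
methods are undefined at zero, so sparsity and compositionality are handled
by a grid of four zero-replacement strategies crossed with five
normalizations — the 20 ``NM_i`` variants that the full-model-selection
stage treats as a human choice to be ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import (
    MaxAbsScaler,
    MinMaxScaler,
    Normalizer,
    QuantileTransformer,
    RobustScaler,
)

from microfms.io_types import RANKS, OTUTable

ZERO_METHODS: tuple[str, ...] = ("none", "pseudo", "multRepl", "bayesMult")
NORM_METHODS: tuple[str, ...] = ("TSS", "CSS", "COM", "rarefy", "clr")

#: NM_1..NM_20 in canonical order: normalization-major, zero-replacement-minor
#: (NM_1 = TSS+none, NM_2 = TSS+pseudo, ..., NM_6 = CSS+pseudo,
#: NM_20 = clr+bayesMult).
NM_VARIANTS: tuple[tuple[str, str], ...] = tuple(
    (norm, zero) for norm in NORM_METHODS for zero in ZERO_METHODS
)

ENV_SCALERS: tuple[str, ...] = (
    "standard",
    "minmax",
    "maxabs",
    "robust",
    "quantile_normal",
    "unitnorm",
)


@dataclass(frozen=True)
class ZeroReplacementConfig:
    """Tunable parameters of the zero-replacement strategies.

    ``mult_delta_fraction`` is the fraction of the per-sample minimum
    nonzero proportion used as the multiplicative-replacement imputed value
    (0.65 is the standard default magnitude for left-censored compositional
    imputation); ``bayes_prior_strength`` is the total strength *s* of the
    uniform Dirichlet prior of the Bayesian-multiplicative treatment.
    """

    pseudo_count: float = 1.0
    mult_delta_fraction: float = 0.65
    bayes_prior_strength: float = 1.0
    pseudo_all_cells: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.mult_delta_fraction < 1:
            raise ValueError("mult_delta_fraction must be in (0, 1)")
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        if self.bayes_prior_strength <= 0:
            raise ValueError("bayes_prior_strength must be positive")


@dataclass(frozen=True)
class PreprocessSpec:
    """One cell of the preprocessing design: NM variant x rank x augmentation."""

    norm_method: str
    zero_method: str
    level: str = "Genus"
    augment: bool = False

    def __post_init__(self) -> None:
        if self.norm_method not in NORM_METHODS:
            raise ValueError(f"unknown normalization {self.norm_method!r}")
        if self.zero_method not in ZERO_METHODS:
            raise ValueError(f"unknown zero replacement {self.zero_method!r}")
        if self.level not in RANKS:
            raise ValueError(f"unknown rank {self.level!r}")

    @property
    def nm_index(self) -> int:
        """1-based index in the canonical NM_1..NM_20 enumeration."""
        return NM_VARIANTS.index((self.norm_method, self.zero_method)) + 1

    @property
    def nm_label(self) -> str:
        return f"NM_{self.nm_index}"

    @classmethod
    def from_nm_index(
        cls, nm_index: int, level: str = "Genus", augment: bool = False
    ) -> "PreprocessSpec":
        if not 1 <= nm_index <= 20:
            raise ValueError("nm_index must be in 1..20")
        norm, zero = NM_VARIANTS[nm_index - 1]
        return cls(norm, zero, level=level, augment=augment)


def make_preprocess_grid(
    levels: tuple[str, ...] = RANKS,
    augment_options: tuple[bool, ...] = (False, True),
) -> list[PreprocessSpec]:
    """The full factorial of preprocessing options.

    With all 5 ranks and both augmentation flags this is the 200-option
    design (20 NM variants x 5 levels x 2) that the FMS tree reasons over.
    """
    return [
        PreprocessSpec(norm, zero, level=level, augment=aug)
        for aug in augment_options
        for level in levels
        for (norm, zero) in NM_VARIANTS
    ]


# ---------------------------------------------------------------------------
# zero replacement


def zero_replace(
    table: OTUTable,
    method: str,
    cfg: ZeroReplacementConfig | None = None,
) -> OTUTable:
    """Impute zero counts so that log-ratio transforms are defined.

    ``pseudo`` sets zero cells to a fixed pseudo count.  ``multRepl``
    imputes, on the proportion scale, delta_k = fraction x (minimum nonzero
    proportion of sample k) and shrinks nonzero proportions multiplicatively
    by (1 - z_k * delta_k) so each sample still sums to one.  ``bayesMult``
    replaces zeros with the posterior-mean proportion under a uniform
    Dirichlet prior of total strength s — a zero taxon gets
    (s/p) / (m_k + s) — and closes the composition multiplicatively.  Both
    imputed tables are rescaled back to the original depths, so ratios
    between originally-nonzero taxa are untouched.
    """
    cfg = cfg or ZeroReplacementConfig()
    if method == "none":
        return table.copy()
    counts = table.data.to_numpy(dtype=float).copy()
    depths = counts.sum(axis=1)
    if method in ("multRepl", "bayesMult") and (counts > 0).sum(axis=1).min() == 0:
        k = int(np.argmin((counts > 0).sum(axis=1)))
        raise ValueError(
            f"sample {table.sample_ids[k]!r} is all zeros; no minimum nonzero "
            "proportion exists"
        )
    if method == "pseudo":
        if cfg.pseudo_all_cells:
            counts = counts + cfg.pseudo_count
        else:
            counts[counts == 0] = cfg.pseudo_count
    elif method == "multRepl":
        props = counts / depths[:, None]
        for k in range(props.shape[0]):
            row = props[k]
            zeros = row == 0
            z = int(zeros.sum())
            if z == 0:
                continue
            # cap keeps z*delta < 1 so the adjusted composition stays positive
            delta = cfg.mult_delta_fraction * min(row[row > 0].min(), 1.0 / z)
            row[~zeros] *= 1.0 - z * delta
            row[zeros] = delta
        counts = props * depths[:, None]
    elif method == "bayesMult":
        s = cfg.bayes_prior_strength
        p = counts.shape[1]
        props = counts / depths[:, None]
        for k in range(props.shape[0]):
            row = props[k]
            zeros = row == 0
            z = int(zeros.sum())
            if z == 0:
                continue
            imputed = (s / p) / (depths[k] + s)
            row[~zeros] *= 1.0 - z * imputed
            row[zeros] = imputed
        counts = props * depths[:, None]
    else:
        raise ValueError(f"unknown zero-replacement method {method!r}")
    out = pd.DataFrame(counts, index=table.sample_ids, columns=table.taxon_ids)
    return OTUTable(out, rank=table.rank)


# ---------------------------------------------------------------------------
# normalization


def _rarefy_counts(
    counts: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Subsample each row without replacement to ``target`` reads."""
    out = np.empty_like(counts)
    for k in range(counts.shape[0]):
        out[k] = rng.multivariate_hypergeometric(counts[k], target)
    return out


def normalize(
    table: OTUTable,
    method: str,
    css_quantile: float = 0.5,
    rarefy_seed: int | None = None,
) -> pd.DataFrame:
    """Apply one of the five normalizations, returning a feature matrix.

    TSS scales each sample to proportions; CSS divides each sample by the
    cumulative sum of its counts up to the per-sample ``css_quantile`` of
    positive counts (then rescales by the median scaling factor so values
    stay on a count-like scale); COM rescales every sample to the minimum
    depth; rarefying subsamples reads without replacement down to the
    minimum depth (seeded); clr takes log-ratios against the per-sample
    geometric mean and requires strictly positive input.
    """
    X = table.data.to_numpy(dtype=float)
    depths = X.sum(axis=1)
    if method == "TSS":
        out = X / depths[:, None]
    elif method == "CSS":
        scale = np.empty(X.shape[0])
        for k in range(X.shape[0]):
            positive = X[k][X[k] > 0]
            q = np.quantile(positive, css_quantile)
            scale[k] = X[k][X[k] <= q].sum()
            if scale[k] <= 0:
                raise ValueError(
                    f"CSS scaling factor is zero for sample {table.sample_ids[k]!r}"
                )
        out = X / scale[:, None] * np.median(scale)
    elif method == "COM":
        out = X * (depths.min() / depths)[:, None]
    elif method == "rarefy":
        target = int(np.floor(depths.min()))
        if (depths < target).any():
            raise ValueError("rarefying target exceeds a sample's depth")
        if rarefy_seed is None:
            raise ValueError("rarefying requires an explicit rarefy_seed")
        # rarefying draws reads, so fractional imputed counts are rounded
        counts = np.rint(X).astype(np.int64)
        counts[(X > 0) & (counts == 0)] = 1  # keep imputed zeros present
        rng = np.random.default_rng(rarefy_seed)
        target = int(min(target, counts.sum(axis=1).min()))
        out = _rarefy_counts(counts, target, rng).astype(float)
    elif method == "clr":
        if (X <= 0).any():
            k, j = np.argwhere(X <= 0)[0]
            raise ValueError(
                "clr requires strictly positive entries; zero at sample "
                f"{table.sample_ids[k]!r}, taxon {table.taxon_ids[j]!r} — "
                "apply a zero-replacement strategy first"
            )
        logX = np.log(X)
        out = logX - logX.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids)


def apply_nm(
    table: OTUTable,
    spec: PreprocessSpec,
    cfg: ZeroReplacementConfig | None = None,
    css_quantile: float = 0.5,
    rarefy_seed: int | None = None,
) -> pd.DataFrame:
    """Zero-replace then normalize per an NM variant.

    The clr+none variant is defined by first imputing zero cells with a
    pseudo count of 1 (the log of zero being undefined, the variant needs
    some implicit handling to exist at all).
    """
    cfg = cfg or ZeroReplacementConfig()
    zero_method = spec.zero_method
    if spec.norm_method == "clr" and zero_method == "none":
        zero_method = "pseudo"
        cfg = ZeroReplacementConfig(
            pseudo_count=1.0,
            mult_delta_fraction=cfg.mult_delta_fraction,
            bayes_prior_strength=cfg.bayes_prior_strength,
        )
    replaced = zero_replace(table, zero_method, cfg)
    return normalize(
        replaced, spec.norm_method, css_quantile=css_quantile, rarefy_seed=rarefy_seed
    )


# ---------------------------------------------------------------------------
# environmental scaling


def scale_environment(
    env: pd.DataFrame,
    method: str = "standard",
    train_index: pd.Index | None = None,
) -> pd.DataFrame:
    """Scale environmental (soil chemistry / population density) features.

    The scaler is fit on the training rows only (``train_index``; all rows
    if omitted) and applied to the full matrix, so held-out samples never
    influence the fitted statistics.
    """
    if method not in ENV_SCALERS:
        raise ValueError(f"unknown scaling method {method!r}; one of {ENV_SCALERS}")
    fit_rows = env.loc[train_index] if train_index is not None else env
    if method == "standard":
        # sample (ddof=1) standard deviation; zero-variance columns map to 0
        mean = fit_rows.mean(axis=0)
        sd = fit_rows.std(axis=0, ddof=1)
        if (sd == 0).any():
            warnings.warn(
                f"zero-variance columns under standard scaling mapped to 0: "
                f"{sd[sd == 0].index.tolist()}",
                stacklevel=2,
            )
        out = (env - mean).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
        return out
    if method == "minmax":
        scaler = MinMaxScaler()
    elif method == "maxabs":
        scaler = MaxAbsScaler()
    elif method == "robust":
        scaler = RobustScaler()
    elif method == "quantile_normal":
        scaler = QuantileTransformer(
            output_distribution="normal",
            n_quantiles=min(1000, len(fit_rows)),
            random_state=0,
        )
    else:  # unitnorm scales each row, nothing to fit
        out = Normalizer(norm="l2").fit_transform(env)
        return pd.DataFrame(out, index=env.index, columns=env.columns)
    scaler.fit(fit_rows)
    return pd.DataFrame(scaler.transform(env), index=env.index, columns=env.columns)


# ---------------------------------------------------------------------------
# binarization


def binarize_disease(values: pd.Series) -> pd.Series:
    """Label 1 where disease severity is > 0, 0 where exactly 0, NA kept."""
    numeric = pd.Series(values, copy=True).astype(float)
    if (numeric.dropna() < 0).any():
        bad = numeric.index[numeric < 0].tolist()
        raise ValueError(f"negative disease severity at samples {bad}")
    labels = (numeric > 0).astype("float").where(numeric.notna())
    return labels.astype("Int64")


def binarize_yield(values: pd.Series, varieties: pd.Series) -> pd.Series:
    """Binarize yield against the variety-specific median.

    Low yield (label 0) is a value below the median of the same potato
    variety; high yield (label 1) is above it.  A value exactly at the
    median joins class 0 so every labeled sample gets a label.  Varieties
    with fewer than two observed yields are left unlabeled.
    """
    values = pd.Series(values, copy=True).astype(float)
    varieties = pd.Series(varieties).reindex(values.index)
    observed = values.notna()
    if varieties[observed].isna().any():
        bad = values.index[observed & varieties.isna()].tolist()
        raise ValueError(f"missing variety for samples {bad}")
    labels = pd.Series(pd.NA, index=values.index, dtype="Int64")
    for variety, group in values[observed].groupby(varieties[observed]):
        if len(group) < 2:
            warnings.warn(
                f"variety {variety!r} has {len(group)} sample(s); left unlabeled",
                stacklevel=2,
            )
            continue
        median = group.median()
        labels.loc[group.index] = (group > median).astype(int)
    return labels


# ---------------------------------------------------------------------------
# alpha diversity


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= rare_threshold]
    abundant = counts[counts > rare_threshold]
    s_rare, s_abund = len(rare), len(abundant)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if f1 == n_rare:
        raise ValueError("ACE undefined: all rare taxa are singletons")
    c_ace = 1.0 - f1 / n_rare
    freqs = np.bincount(rare.astype(int), minlength=rare_threshold + 1)
    sum_term = sum(i * (i - 1) * freqs[i] for i in range(1, rare_threshold + 1))
    gamma2 = max(
        s_rare / c_ace * sum_term / (n_rare * (n_rare - 1)) - 1.0, 0.0
    )
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


ALPHA_INDICES: tuple[str, ...] = ("Chao1", "ACE", "Shannon", "Simpson", "InvSimpson")


def alpha_diversity(
    table: OTUTable,
    index: str = "Shannon",
    rarefy_seed: int = 0,
    rarefy_first: bool = True,
) -> pd.Series:
    """Per-sample within-sample diversity, after rarefying to minimum depth.

    Shannon is -sum p ln p (natural log), Simpson is 1 - sum p^2,
    InvSimpson is 1 / sum p^2; Chao1 uses the bias-corrected estimator
    S_obs + f1(f1-1)/(2(f2+1)); ACE is the abundance-based coverage
    estimator with the standard rare-taxon threshold of 10.
    """
    if index not in ALPHA_INDICES:
        raise ValueError(f"unknown alpha-diversity index {index!r}")
    counts = np.rint(table.data.to_numpy(dtype=float)).astype(np.int64)
    if (counts.sum(axis=1) == 0).any():
        k = int(np.argmin(counts.sum(axis=1)))
        raise ValueError(f"sample {table.sample_ids[k]!r} is empty")
    if rarefy_first:
        rng = np.random.default_rng(rarefy_seed)
        counts = _rarefy_counts(counts, int(counts.sum(axis=1).min()), rng)
    values = np.empty(counts.shape[0])
    for k, row in enumerate(counts):
        row = row[row > 0]
        p = row / row.sum()
        if index == "Shannon":
            values[k] = -(p * np.log(p)).sum()
        elif index == "Simpson":
            values[k] = 1.0 - (p**2).sum()
        elif index == "InvSimpson":
            values[k] = 1.0 / (p**2).sum()
        elif index == "Chao1":
            values[k] = _chao1(row)
        else:
            values[k] = _ace(row)
    return pd.Series(values, index=table.sample_ids, name=index)


def alpha_diversity_matrix(
    table: OTUTable, rarefy_seed: int = 0
) -> pd.DataFrame:
    """All five alpha-diversity indices as a samples x indices matrix."""
    return pd.concat(
        [alpha_diversity(table, ix, rarefy_seed=rarefy_seed) for ix in ALPHA_INDICES],
        axis=1,
    )


# ---------------------------------------------------------------------------
# splitting


def split_train_test(
    X: pd.DataFrame,
    y: pd.Series,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.Index, pd.Index]:
    """Stratified train/test split (80/20 by default); returns index sets."""
    y = y.loc[X.index]
    if y.isna().any():
        raise ValueError("labels contain missing values; drop them before splitting")
    if len(y) < 5:
        raise ValueError("need at least 5 labeled samples to split")
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError("both classes must be present")
    if (class_counts < 2).any():
        raise ValueError("stratification impossible: a class has a single sample")
    n_test = int(round(test_fraction * len(y)))
    train_idx, test_idx = train_test_split(
        X.index,
        test_size=n_test,
        stratify=y.astype(int).to_numpy(),
        random_state=seed,
    )
    return pd.Index(train_idx), pd.Index(test_idx)
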