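"""Leakage-safe Gaussian data augmentation for imbalanced training sets.

Augmentation is applied to the training split only: augmenting before
splitting would leak near-copies of test samples into training.  Synthetic
rows are built per (variety, label) subset as an original row plus Gaussian
noise with mean mu/100 and standard deviation sigma/100, where mu and sigma
are the subset-specific per-feature mean and standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AugmentSubsetStats:
    """Per-(variety, label) feature statistics used to draw the noise."""

    variety: object
    label: int
    mu: np.ndarray
    sigma: np.ndarray
    n_subset: int


def augment_training_set(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    varieties: pd.Series,
    target_per_label: int = 400,
    divisor: float = 100.0,
    seed: int = 0,
    clip_negative: bool = True,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Balance the training set to ``target_per_label`` rows per label.

    For each (variety, label) subset, a synthetic row is a uniformly chosen
    original row of that subset plus elementwise Normal(mu/divisor,
    sigma/divisor) noise.  Subsets of one label are filled round-robin
    until the label reaches the target; originals count toward the target.
    ``clip_negative`` clips synthetic abundances at 0 (appropriate on the
    count/proportion scale; disable for clr-scale features, which are
    legitimately negative).

    Returns ``(X_aug, y_aug, provenance)`` where provenance maps every
    output row id to the source training row id (originals map to
    themselves) — the input to :func:`leakage_check`.
    """
    if not X_train.index.equals(y_train.index):
        raise ValueError("X_train and y_train must share an index")
    varieties = pd.Series(varieties).reindex(X_train.index)
    if varieties.isna().any():
        raise ValueError("missing variety for some training samples")
    labels = sorted(pd.Series(y_train).astype(int).unique())
    if len(labels) < 2:
        raise ValueError(f"training set has a single label {labels}; both required")
    counts = y_train.astype(int).value_counts()
    over = counts[counts > target_per_label]
    if len(over):
        raise ValueError(
            f"labels {over.index.tolist()} already exceed target_per_label="
            f"{target_per_label}; originals are retained, cannot downsample"
        )

    rng = np.random.default_rng(seed)
    columns = X_train.columns
    stats: dict[tuple[object, int], AugmentSubsetStats] = {}
    subsets: dict[int, list[tuple[object, pd.Index]]] = {lab: [] for lab in labels}
    for (variety, label), idx in X_train.groupby(
        [varieties, y_train.astype(int)], observed=True, sort=True
    ).groups.items():
        label = int(label)
        sub = X_train.loc[idx]
        sigma = sub.std(axis=0, ddof=1).to_numpy()
        if len(sub) == 1:
            warnings.warn(
                f"subset (variety={variety!r}, label={label}) has one sample; "
                "sigma treated as 0",
                stacklevel=2,
            )
            sigma = np.zeros(sub.shape[1])
        stats[(variety, label)] = AugmentSubsetStats(
            variety, label, sub.mean(axis=0).to_numpy(), sigma, len(sub)
        )
        subsets[label].append((variety, pd.Index(idx)))

    new_rows, new_labels, new_sources, new_ids = [], [], [], []
    for label in labels:
        n_needed = target_per_label - int(counts.get(label, 0))
        label_subsets = subsets[label]
        for i in range(n_needed):
            variety, idx = label_subsets[i % len(label_subsets)]
            st = stats[(variety, label)]
            source = idx[rng.integers(len(idx))]
            noise = rng.normal(st.mu / divisor, st.sigma / divisor)
            row = X_train.loc[source].to_numpy(dtype=float) + noise
            if clip_negative:
                row = np.clip(row, 0.0, None)
            new_rows.append(row)
            new_labels.append(label)
            new_sources.append(source)
            new_ids.append(f"aug_{label}_{i}")

    X_new = pd.DataFrame(new_rows, index=new_ids, columns=columns)
    X_aug = pd.concat([X_train, X_new])
    y_aug = pd.concat(
        [y_train.astype(int), pd.Series(new_labels, index=new_ids, dtype=int)]
    )
    provenance = pd.concat(
        [
            pd.Series(X_train.index, index=X_train.index),
            pd.Series(new_sources, index=new_ids),
        ]
    )
    return X_aug, y_aug, provenance


def leakage_check(
    train_ids: pd.Index,
    test_ids: pd.Index,
    provenance: pd.Series,
) -> bool:
    """True iff no training row (original or synthetic) descends from a test row.

    ``provenance`` maps each augmented-training-set row id to its source
    sample id; the pipeline asserts this after every augmentation step.
    """
    if provenance is None or len(provenance) == 0:
        raise ValueError("missing provenance")
    missing = pd.Index(train_ids).difference(provenance.index)
    if len(missing):
        raise ValueError(f"rows without provenance: {missing.tolist()}")
    sources = pd.Index(provenance.loc[pd.Index(train_ids)])
    return not sources.isin(pd.Index(test_ids)).any()
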