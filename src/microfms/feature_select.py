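"""Dual feature importance: ML strategies and differential network degree.

Two complementary views nominate predictive taxa.  Seven ML strategies
each pick a same-sized pool of candidates and the per-taxon ``TOTAL``
counts how many strategies agree; separately, sparse microbial association
networks are estimated per class and taxa are ranked by the absolute
difference of their weighted node degrees between the two networks.  A
taxon's combined score is 0 (neither), 1 (ML only), 2 (network only) or
3 (both) — score-3 taxa are the consensus predictors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.covariance import graphical_lasso
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

STRATEGIES: tuple[str, ...] = (
    "anova_f",
    "mutual_info",
    "rfe_logistic",
    "rfe_tree",
    "rfe_gboost",
    "rfe_rf",
    "max_abundance",
)


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the sparse association-network estimator.

    The estimator is a rank-based Gaussian-copula pipeline: modified-clr
    transform, Kendall-tau correlation mapped through sin(pi*tau/2),
    projection to the nearest positive-semidefinite correlation, then a
    graphical-lasso sparse precision at ``sparsity_lambda``.
    """

    sparsity_lambda: float = 0.1
    psd_projection: bool = True
    transform: str = "mclr"
    min_samples: int = 10

    def __post_init__(self) -> None:
        if self.sparsity_lambda <= 0:
            raise ValueError("sparsity_lambda must be positive")


@dataclass(frozen=True)
class FeatureSelectionConfig:
    top_fraction: float = 0.30
    k: int | None = None  # per-strategy pool size; default ceil(0.3 * p)
    rfe_step: float = 0.1
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")

    def pool_size(self, p: int) -> int:
        k = self.k if self.k is not None else math.ceil(self.top_fraction * p)
        if k > p:
            raise ValueError(f"k={k} exceeds number of features p={p}")
        return k


@dataclass
class MicrobialNetwork:
    """A weighted association network over taxa for one class.

    ``partial_corr`` holds the partial correlations r_ij from the sparse
    precision; edges exist where r_ij != 0 and carry the similarity weight
    1 - sqrt(0.5 * (1 - r_ij)) of the signed-distance metric (1 at r=1,
    ~0.293 at r=0, 0 at r=-1).
    """

    taxa: pd.Index
    partial_corr: np.ndarray
    similarity: np.ndarray

    @property
    def degree(self) -> pd.Series:
        """Weighted node degree: the sum of incident edge similarities."""
        return pd.Series(self.similarity.sum(axis=0), index=self.taxa, name="degree")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.taxa)
        for i, j in zip(*np.nonzero(np.triu(self.similarity, k=1))):
            g.add_edge(
                self.taxa[i],
                self.taxa[j],
                weight=float(self.similarity[i, j]),
                partial_corr=float(self.partial_corr[i, j]),
            )
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (self.taxa[i], self.taxa[j], self.similarity[i, j], self.partial_corr[i, j])
            for i, j in zip(*np.nonzero(np.triu(self.similarity, k=1)))
        ]
        return pd.DataFrame(
            rows, columns=["taxon_a", "taxon_b", "similarity", "partial_corr"]
        )


def signed_distance_similarity(r: np.ndarray | float) -> np.ndarray | float:
    """Similarity 1 - sqrt(0.5*(1-r)) of a partial correlation r in [-1, 1]."""
    return 1.0 - np.sqrt(0.5 * (1.0 - np.asarray(r, dtype=float)))


# ---------------------------------------------------------------------------
# ML strategies


def ml_feature_scores(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: FeatureSelectionConfig | None = None,
) -> pd.DataFrame:
    """Run the seven ML selection strategies and tally per-taxon agreement.

    Strategies 1-2 are filter scores (ANOVA F, mutual information); 3-6 are
    recursive feature elimination under four estimators (regularized
    logistic regression, decision tree, gradient boosting, random forest);
    strategy 7 keeps taxa whose column maximum lies in the top 30% of all
    column maxima.  Each strategy nominates ``k = ceil(0.3*p)`` taxa.
    ``TOTAL`` is the number of nominating strategies; the top 30% of taxa by
    TOTAL (ties broken by F statistic, then taxon id) are ``ml_selected``.
    """
    cfg = cfg or FeatureSelectionConfig()
    # canonical column order: tree-based RFE tie-breaks depend on feature
    # position, so sorting makes the scores permutation-invariant
    X = X[sorted(X.columns)]
    y = pd.Series(y).loc[X.index].astype(int)
    if y.nunique() < 2:
        raise ValueError("y is constant; feature scoring requires both classes")
    p = X.shape[1]
    k = cfg.pool_size(p)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()

    out = pd.DataFrame(index=X.columns)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns give F = 0 / NaN
        f_stat, _ = f_classif(Xv, yv)
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    out["anova_f"] = _top_k_mask(pd.Series(f_stat, index=X.columns), k)

    mi = mutual_info_classif(Xv, yv, random_state=cfg.seed)
    out["mutual_info"] = _top_k_mask(pd.Series(mi, index=X.columns), k)

    step = max(1, int(math.ceil(cfg.rfe_step * p))) if cfg.rfe_step < 1 else int(cfg.rfe_step)
    estimators = {
        "rfe_logistic": LogisticRegression(max_iter=2000),
        "rfe_tree": DecisionTreeClassifier(random_state=cfg.seed),
        "rfe_gboost": GradientBoostingClassifier(
            random_state=cfg.seed, n_estimators=50
        ),
        "rfe_rf": RandomForestClassifier(random_state=cfg.seed, n_estimators=100),
    }
    for name, est in estimators.items():
        rfe = RFE(est, n_features_to_select=k, step=step)
        rfe.fit(Xv, yv)
        out[name] = rfe.support_

    out["max_abundance"] = _top_k_mask(X.max(axis=0), k)

    out["TOTAL"] = out[list(STRATEGIES)].sum(axis=1).astype(int)
    out["f_statistic"] = f_stat

    # stable sort over a taxon-id-sorted frame: ties in (TOTAL, F) fall back
    # to lexicographic taxon id, making the cut deterministic
    order = out.sort_index().sort_values(
        by=["TOTAL", "f_statistic"], ascending=[False, False], kind="mergesort"
    )
    n_select = math.ceil(cfg.top_fraction * p)
    out["ml_selected"] = out.index.isin(order.index[:n_select])
    return out.loc[order.index]


def _top_k_mask(scores: pd.Series, k: int) -> pd.Series:
    """Boolean mask of the k highest scores (ties broken by taxon id)."""
    ranked = scores.sort_index().sort_values(ascending=False, kind="mergesort")
    return scores.index.isin(ranked.index[:k])


# ---------------------------------------------------------------------------
# network strategy


def _nearest_psd_correlation(C: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh((C + C.T) / 2)
    vals = np.clip(vals, eps, None)
    C = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def mclr_transform(X: pd.DataFrame) -> pd.DataFrame:
    """Modified centered log-ratio: clr on positive entries, zeros kept.

    Positive entries of each sample are clr-transformed among themselves
    and the whole matrix of transformed values is shifted so positives are
    strictly greater than zero; structural zeros stay at exactly 0.
    """
    V = X.to_numpy(dtype=float).copy()
    mask = V > 0
    out = np.zeros_like(V)
    for i in range(V.shape[0]):
        pos = mask[i]
        if not pos.any():
            raise ValueError("mclr undefined on an all-zero sample")
        logs = np.log(V[i, pos])
        out[i, pos] = logs - logs.mean()
    positives = out[mask]
    if positives.size and positives.min() <= 0:
        out[mask] = positives - positives.min() + 1.0
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def estimate_class_network(
    X_class: pd.DataFrame,
    cfg: NetworkConfig | None = None,
) -> MicrobialNetwork:
    """Estimate a sparse microbial association network from one class.

    Kendall's tau on the mclr-transformed abundances is mapped through
    sin(pi*tau/2) (the Gaussian-copula bridge), projected to the nearest
    positive-semidefinite correlation, and a graphical lasso at
    ``sparsity_lambda`` yields a sparse precision Omega.  Partial
    correlations r_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) define the
    edges; edge weights are the signed-distance similarities.
    """
    cfg = cfg or NetworkConfig()
    n, p = X_class.shape
    if n < cfg.min_samples:
        raise ValueError(
            f"need at least {cfg.min_samples} samples per class; got {n}"
        )
    Z = mclr_transform(X_class) if cfg.transform == "mclr" else X_class.astype(float)
    Zv = Z.to_numpy()

    tau = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            t = kendalltau(Zv[:, i], Zv[:, j]).statistic
            tau[i, j] = tau[j, i] = 0.0 if np.isnan(t) else t
    C = np.sin(np.pi * tau / 2.0)
    np.fill_diagonal(C, 1.0)
    if cfg.psd_projection:
        C = _nearest_psd_correlation(C)

    try:
        _, precision = graphical_lasso(C, alpha=cfg.sparsity_lambda, max_iter=500)
    except FloatingPointError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"graphical lasso did not converge at lambda={cfg.sparsity_lambda}: {exc}"
        ) from exc

    d = np.sqrt(np.diag(precision))
    r = -precision / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    r[np.abs(r) < 1e-10] = 0.0
    r = np.clip(r, -1.0, 1.0)
    similarity = np.where(r != 0.0, signed_distance_similarity(r), 0.0)
    np.fill_diagonal(similarity, 0.0)
    return MicrobialNetwork(taxa=X_class.columns, partial_corr=r, similarity=similarity)


def network_degree_difference(
    net0: MicrobialNetwork,
    net1: MicrobialNetwork,
    top_fraction: float = 0.30,
) -> pd.DataFrame:
    """Rank taxa by |degree_0 - degree_1| between class-conditional networks.

    The top 30% by degree difference (ties broken by taxon id) are the
    network-selected taxa.
    """
    if not net0.taxa.equals(net1.taxa):
        raise ValueError("networks are defined over different taxon sets")
    delta = (net0.degree - net1.degree).abs().rename("degree_difference")
    out = pd.DataFrame(
        {"degree_0": net0.degree, "degree_1": net1.degree, "degree_difference": delta}
    )
    n_select = math.ceil(top_fraction * len(delta))
    ranked = delta.sort_values(ascending=False, kind="mergesort")
    out["net_selected"] = out.index.isin(ranked.index[:n_select])
    return out.sort_values("degree_difference", ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# combination and predictor sets


def combine_feature_scores(
    ml_selected: pd.Series,
    net_selected: pd.Series,
) -> pd.Series:
    """Combined score: 0 neither, 1 ML only, 2 network only, 3 both."""
    ml_selected = pd.Series(ml_selected)
    net_selected = pd.Series(net_selected)
    if not ml_selected.index.equals(net_selected.index):
        raise ValueError("selection masks are not aligned")
    return (ml_selected.astype(int) + 2 * net_selected.astype(int)).rename("score")


PREDICTOR_SETS: tuple[str, ...] = (
    "ALL-OTU",
    "OTU-S0",
    "OTU-S1",
    "OTU-S2",
    "OTU-S3",
    "Alpha",
    "Soil",
    "DS",
    "Soil+DS",
    "Alpha+Soil",
    "Alpha+Soil+DS",
    "OTU-S3+Soil",
    "OTU-S3+DS",
    "OTU-S3+Soil+DS",
)


def build_predictor_set(
    name: str,
    otu_matrix: pd.DataFrame,
    scores: pd.Series | None = None,
    alpha: pd.DataFrame | None = None,
    soil: pd.DataFrame | None = None,
    density: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble a named predictor matrix by column concatenation.

    The OTU-S0 control is subsampled (seeded) to the same column count as
    OTU-S3 so the score-0 and score-3 models compare equal-width designs.
    """
    if name not in PREDICTOR_SETS:
        raise ValueError(f"unknown predictor set {name!r}; one of {PREDICTOR_SETS}")

    def _need(component: pd.DataFrame | pd.Series | None, label: str):
        if component is None:
            raise ValueError(f"predictor set {name!r} requires component {label!r}")
        return component

    parts: list[pd.DataFrame] = []
    if name == "ALL-OTU":
        parts.append(otu_matrix)
    elif name.startswith("OTU-S"):
        s = _need(scores, "scores")
        s = pd.Series(s).reindex(otu_matrix.columns)
        want = int(name[5])
        cols = s.index[s == want]
        if want == 0:
            width = int((s == 3).sum())
            rng = np.random.default_rng(seed)
            cols = pd.Index(
                rng.choice(cols, size=min(width, len(cols)), replace=False)
            )
        parts.append(otu_matrix[cols])
    if "Alpha" in name:
        parts.append(_need(alpha, "alpha"))
    if "Soil" in name:
        parts.append(_need(soil, "soil"))
    if name == "DS" or name.endswith("+DS"):
        parts.append(_need(density, "density"))
    return pd.concat(parts, axis=1)
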