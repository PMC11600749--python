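"""Full model selection: ranking human preprocessing choices with a CART.

Every preprocessing choice — augmentation on/off, which of the 20 NM
(normalization x zero replacement) variants, which taxonomic rank — is a
factor, and the achieved weighted F1 of the downstream classifier is the
response.  A depth-limited regression tree over one-hot factor indicators
then exposes which human decisions move performance the most: the root
split is the single most consequential choice, and each leaf is a bundle
of options with its mean score and the share of the design it covers.

The tree is a hand-written greedy CART (squared-error criterion) so that
tie-breaking between equally good splits is deterministic: candidate
indicators are tried in factor order (Aug, NM_1..NM_20, then ranks
coarsest-first) and the first minimizer wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from microfms.io_types import RANKS

FACTOR_COLUMNS = ("augment", "nm_index", "level")


def build_fms_table(results: pd.DataFrame, response: str) -> pd.DataFrame:
    """One row per preprocessing option with its achieved weighted F1.

    ``results`` is a tidy benchmark table (as produced by
    :func:`microfms.model_eval.run_benchmark`).  Rows are filtered to
    ``response``; duplicate factor combinations are an error, and missing
    cells of the expected full factorial are reported in the returned
    frame's ``attrs["missing_cells"]``.
    """
    sub = results[results["response"] == response]
    if sub.empty:
        raise ValueError(f"no benchmark rows for response {response!r}")
    table = sub[["augment", "nm_index", "level", "weighted_f1"]].copy()
    table["augment"] = table["augment"].astype(int)
    dup = table.duplicated(subset=list(FACTOR_COLUMNS))
    if dup.any():
        raise ValueError(
            f"duplicated preprocessing cells: "
            f"{table.loc[dup, list(FACTOR_COLUMNS)].to_dict('records')}"
        )
    levels = [lv for lv in RANKS if lv in set(table["level"])]
    expected = {
        (aug, nm, lv)
        for aug in sorted(table["augment"].unique())
        for nm in sorted(table["nm_index"].unique())
        for lv in levels
    }
    present = set(map(tuple, table[list(FACTOR_COLUMNS)].to_numpy()))
    table = table.reset_index(drop=True)
    table.attrs["missing_cells"] = sorted(expected - present)
    return table


def one_hot_factors(table: pd.DataFrame) -> pd.DataFrame:
    """One-hot indicator design: Aug, NM_1..NM_20, then rank indicators."""
    out = pd.DataFrame(index=table.index)
    out["Aug"] = table["augment"].astype(int)
    for nm in sorted(pd.unique(table["nm_index"])):
        out[f"NM_{int(nm)}"] = (table["nm_index"] == nm).astype(int)
    for lv in RANKS:
        if (table["level"] == lv).any():
            out[lv] = (table["level"] == lv).astype(int)
    return out


@dataclass
class TreeNode:
    """A node of the FMS regression tree.

    ``feature`` is the one-hot indicator tested at an internal node; the
    left child holds rows where the indicator is 0 (condition
    ``feature = 0`` true), the right child rows where it is 1.
    """

    mean: float
    n: int
    coverage: float  # fraction of all preprocessing options under this node
    depth: int
    feature: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class RegressionTree:
    root: TreeNode
    feature_names: list[str]

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, prefix: str) -> None:
            stats = (
                f"mean={node.mean:.3f}, options={node.coverage * 100:.1f}%, n={node.n}"
            )
            if node.is_leaf:
                lines.append(f"{prefix}leaf: {stats}")
            else:
                lines.append(f"{prefix}{node.feature} = 0? ({stats})")
                walk(node.left, prefix + "  [yes] ")
                walk(node.right, prefix + "  [no]  ")

        walk(self.root, "")
        return "\n".join(lines)

    def to_dot(self) -> str:
        lines = ["digraph fms_tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: TreeNode) -> int:
            nid = counter[0]
            counter[0] += 1
            label = f"mean={node.mean:.3f}\\noptions={node.coverage * 100:.1f}%"
            if not node.is_leaf:
                label = f"{node.feature} = 0\\n{label}"
            lines.append(f'  n{nid} [label="{label}"];')
            if not node.is_leaf:
                l, r = walk(node.left), walk(node.right)
                lines.append(f'  n{nid} -> n{l} [label="true"];')
                lines.append(f'  n{nid} -> n{r} [label="false"];')
            return nid

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


def _split_sse(y: np.ndarray, mask: np.ndarray) -> float:
    """Total within-child sum of squared errors of a candidate split."""
    left, right = y[mask], y[~mask]
    sse = 0.0
    for part in (left, right):
        if len(part):
            sse += float(((part - part.mean()) ** 2).sum())
    return sse


def fit_fms_tree(
    table: pd.DataFrame,
    max_depth: int = 4,
    min_split: int = 2,
    min_leaf: int = 1,
) -> RegressionTree:
    """Greedy CART over one-hot preprocessing indicators.

    At each node the binary indicator split minimizing the total child SSE
    is chosen (ties resolved by factor order: Aug, NM_1..NM_20, ranks
    coarsest-first); recursion stops at ``max_depth`` or when no split
    satisfies ``min_split``/``min_leaf``.  A constant response yields a
    single-leaf tree.
    """
    if len(table) < 1:
        raise ValueError("empty FMS table")
    X = one_hot_factors(table)
    y = table["weighted_f1"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("weighted_f1 contains missing values")
    features = list(X.columns)
    Xv = X.to_numpy(dtype=int)
    n_root = len(y)

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        yy = y[rows]
        node = TreeNode(
            mean=float(yy.mean()),
            n=len(rows),
            coverage=len(rows) / n_root,
            depth=depth,
        )
        if depth >= max_depth or len(rows) < min_split or np.ptp(yy) == 0:
            return node
        best_sse, best_j = None, None
        for j in range(len(features)):
            mask = Xv[rows, j] == 0  # left child: indicator 0
            n_left = int(mask.sum())
            if n_left < min_leaf or len(rows) - n_left < min_leaf:
                continue
            sse = _split_sse(yy, mask)
            if best_sse is None or sse < best_sse - 1e-12:
                best_sse, best_j = sse, j
        if best_j is None:
            return node
        mask = Xv[rows, best_j] == 0
        node.feature = features[best_j]
        node.left = grow(rows[mask], depth + 1)
        node.right = grow(rows[~mask], depth + 1)
        return node

    root = grow(np.arange(n_root), 0)
    return RegressionTree(root=root, feature_names=features)


def summarize_tree(tree: RegressionTree) -> pd.DataFrame:
    """Ranked leaf report: condition path, mean weighted F1, option coverage.

    Leaves are sorted by mean weighted F1 descending.  A path step reads as
    the decision taken: the factor name when the indicator was 1 (e.g.
    ``Aug`` = with augmentation, ``NM_6`` = that NM variant chosen) and
    ``not <factor>`` when it was 0.
    """
    rows = []

    def walk(node: TreeNode, path: list[str]) -> None:
        if node.is_leaf:
            rows.append(
                {
                    "path": ", ".join(path) if path else "(root)",
                    "mean_weighted_f1": node.mean,
                    "options_pct": node.coverage * 100.0,
                    "n_options": node.n,
                    "depth": node.depth,
                }
            )
            return
        walk(node.left, path + [f"not {node.feature}"])
        walk(node.right, path + [node.feature])

    walk(tree.root, [])
    out = pd.DataFrame(rows).sort_values(
        "mean_weighted_f1", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)
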