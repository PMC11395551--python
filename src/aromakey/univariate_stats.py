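"""One-way ANOVA with Fisher-LSD letters, 2^-ddCt fold change, and HCA.

The Fisher-LSD procedure tests every pair of groups with two-sided
t-tests sharing the pooled within-group mean square; groups are then
summarized with a compact letter display built by the insert-and-absorb
algorithm, so that two groups share a letter exactly when their pairwise
difference is not significant. By default the pairwise tests are
*protected*: they only run when the omnibus F-test is itself significant
(otherwise every group shares one letter); the unprotected variant is a
flag away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

import string


@dataclass
class AnovaLSDResult:
    group_means: dict[str, float]
    mse: float
    df_error: int
    f_statistic: float
    f_p_value: float
    pairwise_p: dict[frozenset, float]
    letters: dict[str, str]
    alpha: float


@dataclass(frozen=True)
class FoldChange:
    delta_delta_ct: float
    fold: float  # 2 ** (-ddCt)


@dataclass
class DendrogramResult:
    linkage_matrix: np.ndarray          # scipy (n-1) × 4 merge tree
    labels: tuple[str, ...]
    flat_clusters: dict[str, int]       # label -> 1..k
    newick: str


# ---------------------------------------------------------------------------
# Fisher-LSD with compact letter display
# ---------------------------------------------------------------------------

def _insert_and_absorb(
    ordered_groups: Sequence[str],
    sig_pairs: set[frozenset],
) -> dict[str, str]:
    """Compact letter display: split letter columns on significant pairs,
    absorb redundant columns, letter the survivors deterministically."""
    columns: list[set[str]] = [set(ordered_groups)]
    pos = {g: i for i, g in enumerate(ordered_groups)}
    for pair in sorted(sig_pairs, key=lambda p: sorted(pos[g] for g in p)):
        a, b = sorted(pair, key=lambda g: pos[g])
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop duplicates and strict subsets
        new_columns = [c for c in new_columns if c]
        keep: list[set[str]] = []
        for c in new_columns:
            if any(c < other or c == other for other in keep):
                continue
            keep = [k for k in keep if not k < c]
            keep.append(c)
        columns = keep
    columns.sort(key=lambda c: min(pos[g] for g in c))
    if len(columns) > len(string.ascii_lowercase):
        raise ValueError("too many letter columns for a single alphabet")
    letters = {g: "" for g in ordered_groups}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def anova_lsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    protected: bool = True,
) -> AnovaLSDResult:
    """One-way ANOVA followed by Fisher-LSD pairwise comparisons.

    ``groups`` maps group name -> replicate values. With
    ``protected=True`` (the default) a non-significant omnibus F leaves
    all groups sharing letter "a".
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("need at least 2 replicates per group")

    k = len(names)
    n_total = sum(len(v) for v in data.values())
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_between = k - 1
    df_error = n_total - k
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere; MSE degenerate")
    mse = ss_within / df_error
    f_stat = (ss_between / df_between) / mse
    f_p = float(stats.f.sf(f_stat, df_between, df_error))

    means = {g: float(v.mean()) for g, v in data.items()}
    pairwise: dict[frozenset, float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(mse * (1 / len(data[a]) + 1 / len(data[b])))
            t = (means[a] - means[b]) / se
            pairwise[frozenset((a, b))] = float(
                2 * stats.t.sf(abs(t), df_error))

    if protected and f_p > alpha:
        sig_pairs: set[frozenset] = set()
    else:
        sig_pairs = {pair for pair, p in pairwise.items() if p <= alpha}

    ordered = sorted(names, key=lambda g: -means[g])  # highest mean gets 'a'
    letters = _insert_and_absorb(ordered, sig_pairs)
    return AnovaLSDResult(
        group_means=means,
        mse=float(mse),
        df_error=df_error,
        f_statistic=float(f_stat),
        f_p_value=f_p,
        pairwise_p=pairwise,
        letters=letters,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# 2^-ddCt fold change
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct_target_case: float | Sequence[float],
    ct_ref_case: float | Sequence[float],
    ct_target_ctrl: float | Sequence[float],
    ct_ref_ctrl: float | Sequence[float],
) -> FoldChange:
    """Relative expression by the 2^-ddCt method.

    Replicate Ct values are averaged before differencing:
    ``ddCt = (Ct_target,case − Ct_ref,case) − (Ct_target,ctrl − Ct_ref,ctrl)``
    and ``fold = 2^(−ddCt)``.
    """
    vals = [float(np.mean(np.asarray(v, dtype=float)))
            for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)]
    if any(v <= 0 for v in vals):
        raise ValueError("Ct values must be positive")
    ddct = (vals[0] - vals[1]) - (vals[2] - vals[3])
    return FoldChange(delta_delta_ct=ddct, fold=float(2.0 ** (-ddct)))


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def _to_newick(node: hierarchy.ClusterNode, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hca_cluster(
    matrix: np.ndarray,
    labels: Sequence[str],
    k: int,
    distance: str = "euclidean",
    linkage: str = "average",
) -> DendrogramResult:
    """Agglomerative clustering of the rows of ``matrix``.

    Defaults (Euclidean distance, average linkage) mirror common heatmap
    practice. Returns the scipy merge tree, a flat cut at ``k`` clusters
    and a Newick rendering of the dendrogram.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if k > n:
        raise ValueError(f"k={k} exceeds number of items {n}")
    if len(labels) != n:
        raise ValueError("labels must match matrix rows")
    Z = hierarchy.linkage(pdist(matrix, metric=distance), method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    tree = hierarchy.to_tree(Z)
    return DendrogramResult(
        linkage_matrix=Z,
        labels=tuple(labels),
        flat_clusters={lab: int(c) for lab, c in zip(labels, flat)},
        newick=_to_newick(tree, list(labels)) + ";",
    )


def scale_rows(matrix: np.ndarray) -> np.ndarray:
    """Per-row unit-variance scaling (heatmap preprocessing)."""
    matrix = np.asarray(matrix, dtype=float)
    mu = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (matrix - mu) / sd
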