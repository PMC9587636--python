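"""Clustering of significant profiles, membership encoding and heatmap groups.

Significant normalized profiles of each feature (replicate means) are
partitioned by k-means; the per-feature cluster assignments of every well are
then concatenated into a binary *membership vector* — one one-hot block per
feature, all-zero for features where the well was not significant, rendered
like ``0001-010-10`` (cluster 4 of 4 for the first feature, 2 of 3 for the
second, 1 of 2 for the third). Hierarchical clustering of these vectors,
cut at a fixed dendrogram height, yields the heatmap groups used to judge
whether different siRNAs share a phenotype.

With Euclidean distance, two vectors that disagree in a single feature block
differ in two bit positions (distance sqrt(2) ~ 1.414) while disagreement in
two blocks gives distance 2; the default complete-linkage cut at 1.8 hence
merges single-block disagreements and separates two-block ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "MembershipVector",
    "HeatmapGroups",
    "kmeans_profiles",
    "encode_membership",
    "hclust_groups",
    "export_heatmap",
]

DEFAULT_CUT_HEIGHT = 1.8


@dataclass(frozen=True)
class ClusterModel:
    feature: str
    k: int
    centroids: np.ndarray  # (k, n_bins)
    assignments: dict  # well key -> cluster id 1..k
    seed: int
    n_init: int


@dataclass(frozen=True)
class MembershipVector:
    key: tuple
    blocks: tuple[np.ndarray, ...]

    @property
    def bits(self) -> np.ndarray:
        return np.concatenate(self.blocks)

    @property
    def rendered(self) -> str:
        return "-".join("".join(str(int(b)) for b in block) for block in self.blocks)


@dataclass(frozen=True)
class HeatmapGroups:
    linkage: np.ndarray | None  # scipy linkage matrix (None for a single vector)
    cut_height: float
    groups: dict  # well key -> group id (1-based, numbered by tree order)
    leaf_order: tuple  # well keys in dendrogram order


def kmeans_profiles(
    profiles: Mapping[tuple, np.ndarray],
    k: int,
    seed: int = 0,
    n_init: int = 10,
    feature: str = "",
) -> ClusterModel:
    """K-means partition of one feature's significant profiles.

    ``profiles`` maps well keys to (replicate-mean) normalized profiles.
    Lloyd iterations from ``n_init`` seeded initializations; the labeling is
    canonicalized — clusters renumbered 1..k by descending size, ties broken
    by descending centroid norm — so runs with the same seed are identical
    and runs with different seeds are comparable.
    """
    keys = list(profiles)
    if len(keys) < k:
        raise ValueError(f"need at least {k} profiles for k={k}, got {len(keys)}")
    X = np.vstack([profiles[key] for key in keys])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    sizes = np.bincount(labels, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], -norms[c]))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = {key: relabel[int(lab)] for key, lab in zip(keys, labels)}
    centroids = km.cluster_centers_[order]
    return ClusterModel(
        feature=feature, k=k, centroids=centroids, assignments=assignments,
        seed=seed, n_init=n_init,
    )


def encode_membership(
    assignments: Mapping[str, int | None],
    ks: Mapping[str, int],
    feature_order: Sequence[str],
    key: tuple = (),
) -> MembershipVector:
    """One-hot encode a well's per-feature cluster assignments.

    ``assignments[feature]`` is the 1-based cluster id, or None where the
    well's profile was not significant for that feature (all-zero block).
    """
    blocks = []
    for feature in feature_order:
        k = ks[feature]
        block = np.zeros(k, dtype=int)
        cluster = assignments.get(feature)
        if cluster is not None:
            if not 1 <= cluster <= k:
                raise ValueError(f"{feature}: cluster id {cluster} outside 1..{k}")
            block[cluster - 1] = 1
        blocks.append(block)
    return MembershipVector(key=key, blocks=tuple(blocks))


def hclust_groups(
    vectors: Sequence[MembershipVector],
    linkage: str = "complete",
    metric: str = "euclidean",
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> HeatmapGroups:
    """Agglomerate membership vectors and cut the dendrogram into groups.

    Group ids are renumbered by first appearance along the dendrogram leaf
    order, so the numbering is stable and matches the heatmap row order.
    """
    if len(vectors) == 0:
        raise ValueError("need at least one membership vector")
    keys = [v.key for v in vectors]
    if len(vectors) == 1:
        return HeatmapGroups(None, cut_height, {keys[0]: 1}, tuple(keys))
    X = np.vstack([v.bits for v in vectors]).astype(float)
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    leaf_order = [keys[i] for i in hierarchy.leaves_list(Z)]
    raw_by_key = dict(zip(keys, raw))
    renumber: dict[int, int] = {}
    for key in leaf_order:
        renumber.setdefault(raw_by_key[key], len(renumber) + 1)
    groups = {key: renumber[raw_by_key[key]] for key in keys}
    return HeatmapGroups(Z, cut_height, groups, tuple(leaf_order))


def export_heatmap(
    vectors: Sequence[MembershipVector],
    groups: HeatmapGroups,
    annotations: Mapping[tuple, Mapping[str, object]],
    path,
    ks: Mapping[str, int] | None = None,
    feature_order: Sequence[str] | None = None,
    plot_path=None,
) -> pd.DataFrame:
    """Write the heatmap matrix (rows in tree order, columns = membership bits).

    Sidebar columns carry content type and heatmap group so control and
    treatment rows are distinguishable. Optionally renders a PNG heatmap
    when ``plot_path`` is given (requires matplotlib).
    """
    by_key = {v.key: v for v in vectors}
    if feature_order is not None and ks is not None:
        bit_cols = [f"{f}_c{i}" for f in feature_order for i in range(1, ks[f] + 1)]
    else:
        bit_cols = [f"bit{i}" for i in range(len(vectors[0].bits))]
    rows = []
    for key in groups.leaf_order:
        v = by_key[key]
        ann = annotations.get(key, {})
        row = {
            "plate": key[0],
            "well": key[1],
            "content": ann.get("content", ""),
            "rna_id": ann.get("rna_id", ""),
            "gene": ann.get("gene", ""),
            "group": groups.groups[key],
            "vector": v.rendered,
        }
        row.update(dict(zip(bit_cols, v.bits.tolist())))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    if plot_path is not None:
        _plot_heatmap(df, bit_cols, plot_path)
    return df


def _plot_heatmap(df: pd.DataFrame, bit_cols: list[str], plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * len(df))))
    ax.imshow(df[bit_cols].to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xticks(range(len(bit_cols)))
    ax.set_xticklabels(bit_cols, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel("wells (tree order)")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)
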