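"""Pearson-correlation hierarchical clustering and laminar zonation of QISPs.

Profiles are standardized gene-wise (mean 0, SD 1) and clustered
agglomeratively on the correlation distance ``d = 1 - r``.  Because Pearson's
r is invariant to positive affine transforms, two genes with identical
spatial patterns but different staining magnitudes cluster together — the
property that makes correlation distance the natural choice for co-regulation
analysis of radial expression profiles.

Flat cluster labels come from a standard k-cluster cut of the merge tree.
Each cluster's centroid (mean of its members' normalized profiles) is
assigned to a laminar zone — deep (ventricular zone), middle (intermediate
zone) or upper (cortical plate / marginal zone) — by the location of its
peak bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .extraction import N_SROIS

__all__ = [
    "ZoneMap",
    "ClusterTree",
    "ClusterResult",
    "normalize_qisp",
    "is_degenerate",
    "pearson_distance",
    "hierarchical_cluster",
    "cut_clusters",
    "assign_zone",
    "cluster_qisps",
    "group_summary",
    "subset_by_annotation",
    "plot_cluster_heatmap",
]

ZONES = ("deep", "middle", "upper")


@dataclass(frozen=True)
class ZoneMap:
    """Partition of the 20 sROIs into deep / middle / upper compartments.

    The default puts the deep (VZ) compartment at sROIs 1-10, middle (IZ) at
    11-15 and upper (CP + MZ) at 16-20.  Bins are 1-based; each compartment
    must be contiguous, bin 1 must be deep and bin 20 upper.
    """

    deep_bins: tuple[int, ...] = tuple(range(1, 11))
    middle_bins: tuple[int, ...] = tuple(range(11, 16))
    upper_bins: tuple[int, ...] = tuple(range(16, 21))

    def __post_init__(self) -> None:
        all_bins = sorted(self.deep_bins + self.middle_bins + self.upper_bins)
        if all_bins != list(range(1, N_SROIS + 1)):
            raise ValueError("zones must partition sROIs 1..20")
        for bins in (self.deep_bins, self.middle_bins, self.upper_bins):
            b = sorted(bins)
            if b != list(range(b[0], b[-1] + 1)):
                raise ValueError("each zone must be a contiguous bin range")
        if 1 not in self.deep_bins or N_SROIS not in self.upper_bins:
            raise ValueError("deep must contain bin 1 and upper bin 20")

    def zone_of_bin(self, sroi: int) -> str:
        if sroi in self.deep_bins:
            return "deep"
        if sroi in self.middle_bins:
            return "middle"
        return "upper"


def normalize_qisp(profile: Sequence[float]) -> np.ndarray:
    """Gene-wise standardization: ``(x - mean) / SD`` (sample SD, ddof=1).

    Zero-variance profiles map to the zero vector (see :func:`is_degenerate`);
    with correlation distance the standardization affects only centroids, not
    distances.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (N_SROIS,):
        raise ValueError(f"profile must have length {N_SROIS}")
    if is_degenerate(p):
        return np.zeros_like(p)
    return (p - p.mean()) / p.std(ddof=1)


def is_degenerate(profile: Sequence[float]) -> bool:
    """True for zero-variance (constant) profiles, which have no direction."""
    p = np.asarray(profile, dtype=float)
    # exact min == max, not std == 0: the mean of a constant vector is not
    # always representable, leaving std at ~1e-16
    return bool(np.ptp(p) == 0)


def pearson_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Correlation distance ``1 - r`` in [0, 2] over the 20 bins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if is_degenerate(a) or is_degenerate(b):
        raise ValueError("correlation distance undefined for constant profiles")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


@dataclass
class ClusterTree:
    """Agglomerative merge tree over gene profiles.

    ``linkage_matrix`` is in SciPy linkage format; ``leaf_ids`` gives the
    gene id of each leaf index.  ``input_order`` preserves the caller's gene
    order for flat-label numbering.
    """

    linkage_matrix: np.ndarray
    leaf_ids: list[str]
    input_order: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Newick serialization with branch lengths = height differences."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


@dataclass
class ClusterResult:
    """Flat clustering of validated QISPs with laminar zone assignments."""

    tree: ClusterTree
    labels: dict[str, int]
    centroids: dict[int, np.ndarray]
    zone_of_cluster: dict[int, str]
    zone_of_gene: dict[str, str] = field(default_factory=dict)

    def labels_frame(self) -> pd.DataFrame:
        genes = list(self.labels)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "cluster": [self.labels[g] for g in genes],
                "zone": [self.zone_of_gene[g] for g in genes],
            }
        )


def hierarchical_cluster(
    profiles: Mapping[str, Sequence[float]], linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering on the pairwise Pearson distance matrix.

    Genes are processed in lexicographic id order so ties in the distance
    matrix break deterministically.  All profiles must be non-degenerate.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    input_order = list(profiles)
    if len(input_order) < 2:
        raise ValueError("need at least 2 genes to cluster")
    leaf_ids = sorted(input_order)
    X = np.vstack([np.asarray(profiles[g], dtype=float) for g in leaf_ids])
    for g, row in zip(leaf_ids, X):
        if is_degenerate(row):
            raise ValueError(f"gene {g!r} has a constant profile; exclude it")
    # condensed correlation distances, clipped against tiny negative rounding
    n = len(leaf_ids)
    corr = np.corrcoef(X)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    condensed = d[np.triu_indices(n, k=1)]
    condensed = np.maximum(condensed, 0.0)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(linkage_matrix=Z, leaf_ids=leaf_ids, input_order=input_order)


def cut_clusters(tree: ClusterTree, k: int) -> dict[str, int]:
    """Cut the merge tree into exactly ``k`` flat clusters.

    Removes the ``k - 1`` highest merges.  Cluster ids 1..k are numbered by
    the order of each cluster's first member in the caller's original input.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must lie in [1, {tree.n_leaves}]")
    raw = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    raw_of_gene = dict(zip(tree.leaf_ids, raw.tolist()))
    renumber: dict[int, int] = {}
    for g in tree.input_order:
        r = raw_of_gene[g]
        if r not in renumber:
            renumber[r] = len(renumber) + 1
    return {g: renumber[raw_of_gene[g]] for g in tree.input_order}


def assign_zone(centroid: Sequence[float], zones: ZoneMap | None = None) -> str:
    """Zone of a cluster centroid: the compartment holding its peak bin.

    Ties among equal-valued peak bins break toward the more superficial
    (higher-index) bin.  Constant centroids are ``"unassigned"``.
    """
    zones = zones or ZoneMap()
    c = np.asarray(centroid, dtype=float)
    if is_degenerate(c):
        return "unassigned"
    peak_bin = int(np.flatnonzero(c == c.max())[-1]) + 1
    return zones.zone_of_bin(peak_bin)


def cluster_qisps(
    profiles: Mapping[str, Sequence[float]],
    k: int,
    linkage: str = "average",
    zones: ZoneMap | None = None,
) -> ClusterResult:
    """Normalize, cluster, cut and zone-assign a set of profiles.

    Degenerate (constant) profiles are excluded from the tree and appended as
    singleton clusters with zone ``"unassigned"``; ``k`` refers to the cut of
    the non-degenerate tree.
    """
    zones = zones or ZoneMap()
    good = {g: p for g, p in profiles.items() if not is_degenerate(p)}
    degenerate = [g for g in profiles if g not in good]

    normed = {g: normalize_qisp(p) for g, p in good.items()}
    tree = hierarchical_cluster(normed, linkage=linkage)
    labels = cut_clusters(tree, k)

    centroids: dict[int, np.ndarray] = {}
    for cid in sorted(set(labels.values())):
        members = [g for g, c in labels.items() if c == cid]
        centroids[cid] = np.vstack([normed[g] for g in members]).mean(axis=0)
    zone_of_cluster = {cid: assign_zone(c, zones) for cid, c in centroids.items()}

    next_id = max(labels.values(), default=0)
    for g in degenerate:
        next_id += 1
        labels[g] = next_id
        centroids[next_id] = np.zeros(N_SROIS)
        zone_of_cluster[next_id] = "unassigned"

    zone_of_gene = {g: zone_of_cluster[labels[g]] for g in profiles}
    return ClusterResult(
        tree=tree,
        labels=labels,
        centroids=centroids,
        zone_of_cluster=zone_of_cluster,
        zone_of_gene=zone_of_gene,
    )


def group_summary(zone_of_gene: Mapping[str, str]) -> pd.DataFrame:
    """Per-zone gene counts with integer (half-up) and one-decimal percentages."""
    if not zone_of_gene:
        raise ValueError("no genes to summarize")
    total = len(zone_of_gene)
    zones = list(ZONES) + (
        ["unassigned"] if "unassigned" in set(zone_of_gene.values()) else []
    )
    rows = []
    for z in zones:
        count = sum(1 for v in zone_of_gene.values() if v == z)
        pct = 100.0 * count / total
        rows.append(
            {
                "zone": z,
                "count": count,
                "percent": int(np.floor(pct + 0.5)),
                "percent_1dp": round(pct, 1),
            }
        )
    return pd.DataFrame(rows)


def subset_by_annotation(
    genes: Sequence[str],
    annotations: Mapping[str, Iterable[str]],
    term_query: str,
) -> list[str]:
    """Genes carrying an annotation term matching ``term_query``.

    Matching is case-insensitive substring containment (so a query of
    ``"synap"`` catches both ``synapse`` and ``synaptic``).  Input order is
    preserved; genes absent from the table are simply not matched.
    """
    q = term_query.lower()
    out = []
    for g in genes:
        terms = annotations.get(g, ())
        if any(q in str(t).lower() for t in terms):
            out.append(g)
    return out


def annotation_table_to_mapping(df: pd.DataFrame) -> dict[str, set[str]]:
    """Long-format (gene_id, term) table -> gene -> term-set mapping."""
    mapping: dict[str, set[str]] = {}
    for g, t in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(str(g), set()).add(str(t))
    return mapping


def plot_cluster_heatmap(
    result: ClusterResult,
    profiles: Mapping[str, Sequence[float]],
    path: str,
) -> None:
    """Dendrogram + heatmap of normalized profiles in leaf order (PNG).

    Rows are genes ordered as in the dendrogram, columns sROIs 1-20
    (ventricular to pial, left to right); red high, green low.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = hierarchy.leaves_list(result.tree.linkage_matrix)
    genes = [result.tree.leaf_ids[i] for i in order]
    M = np.vstack([normalize_qisp(profiles[g]) for g in genes])

    fig, (ax_tree, ax_map) = plt.subplots(
        1, 2, figsize=(8, max(3, 0.12 * len(genes))),
        gridspec_kw={"width_ratios": [1, 3]},
    )
    hierarchy.dendrogram(
        result.tree.linkage_matrix, orientation="left", ax=ax_tree,
        no_labels=True, color_threshold=0,
    )
    ax_tree.set_axis_off()
    ax_map.imshow(M[::-1], aspect="auto", cmap="RdYlGn_r", interpolation="nearest")
    ax_map.set_xticks([0, 9, 19], labels=["sROI 1", "10", "20"])
    ax_map.set_yticks([])
    ax_map.set_xlabel("ventricular → pial")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
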