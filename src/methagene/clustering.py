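"""Gene modules: hierarchical clustering of methylation profiles with a
hybrid dynamic tree cut.

Genes whose binned methylation profiles share a shape are grouped into
modules. Rows are (optionally) standardised so clustering captures profile
shape rather than absolute level, hierarchically clustered, and the
dendrogram is cut adaptively: instead of one global height, each merge is
examined for a clear separation gap, so the number of modules emerges from
the data. Objects that fit no module form the unassigned pool (module 0);
a second, "hybrid" pass adopts unassigned objects into the nearest module
when their average dissimilarity to it is compatible with the module's own
spread — the tree + dissimilarity combination that defines the hybrid
variant of dynamic tree cutting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from methagene.types import BinnedDensityMatrix

__all__ = ["ModuleAssignment", "cluster_modules", "module_profiles", "hybrid_tree_cut"]

# deep_split 0 (conservative, few modules) .. 4 (aggressive, many): minimum
# relative height gap a merge must exhibit to be split
_GAP_FRACTIONS = (0.40, 0.30, 0.20, 0.12, 0.06)


@dataclass
class ModuleAssignment:
    """Region -> module mapping. Module ids are positive integers ordered
    by decreasing module size; 0 marks unassigned regions (too many missing
    bins, or not adopted by any module)."""

    region_ids: np.ndarray
    labels: np.ndarray
    distance: str
    linkage: str
    min_module_size: int
    deep_split: int

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.labels[self.labels > 0]
        return pd.Series(assigned).value_counts().sort_index()

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region_id": self.region_ids, "module_id": self.labels})


def _subtree_stats(Z: np.ndarray, n: int):
    """Per-node subtree sizes, merge heights, and core scatter (the mean of
    all merge heights inside the subtree), computed bottom-up."""
    n_nodes = 2 * n - 1
    size = np.ones(n_nodes, dtype=int)
    height = np.zeros(n_nodes)
    height_sum = np.zeros(n_nodes)
    n_merges = np.zeros(n_nodes, dtype=int)
    for k in range(n - 1):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        size[n + k] = size[a] + size[b]
        height[n + k] = Z[k, 2]
        height_sum[n + k] = height_sum[a] + height_sum[b] + Z[k, 2]
        n_merges[n + k] = n_merges[a] + n_merges[b] + 1
    with np.errstate(invalid="ignore"):
        core = np.where(n_merges > 0, height_sum / np.maximum(n_merges, 1), 0.0)
    return size, height, core


def _leaves(Z: np.ndarray, n: int, node: int) -> list[int]:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.append(int(Z[v - n, 0]))
            stack.append(int(Z[v - n, 1]))
    return out


def hybrid_tree_cut(
    Z: np.ndarray,
    dist_matrix: np.ndarray,
    min_module_size: int = 20,
    deep_split: int = 2,
) -> np.ndarray:
    """Adaptive dendrogram cut with dissimilarity-based adoption.

    Tree stage: starting from the root, a merge is split into its two
    branches when its height stands clear of both branches' core scatter
    (mean internal merge height) by a gap proportional to the dendrogram
    height (``deep_split`` controls the proportion); branches smaller than
    ``min_module_size`` join the unassigned pool.
    Hybrid stage: each unassigned object is adopted by the module with the
    smallest average dissimilarity, provided that dissimilarity does not
    exceed the module's own average internal dissimilarity by more than a
    fixed factor. Returns integer labels, 0 = unassigned, modules numbered
    by decreasing size.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    n = Z.shape[0] + 1
    if n == 1:
        return np.ones(1, dtype=int)
    size, height, core = _subtree_stats(Z, n)
    root = 2 * n - 2
    root_height = height[root]
    if root_height <= 0:  # all objects identical
        return np.ones(n, dtype=int)
    # a merge separates two clusters when it stands clear of both branches'
    # core scatter (mean internal merge height) by this absolute gap
    min_gap = _GAP_FRACTIONS[deep_split] * root_height

    clusters: list[list[int]] = []
    unassigned: list[int] = []

    stack = [root]
    while stack:
        node = stack.pop()
        if node < n or height[node] <= 0:
            members = _leaves(Z, n, node) if node >= n else [node]
            if len(members) >= min_module_size:
                clusters.append(members)
            else:
                unassigned.extend(members)
            continue
        k = node - n
        a, b = int(Z[k, 0]), int(Z[k, 1])
        h = Z[k, 2]
        if h - core[a] >= min_gap and h - core[b] >= min_gap:
            for child in (a, b):
                if size[child] >= min_module_size:
                    stack.append(child)
                else:
                    unassigned.extend(_leaves(Z, n, child) if child >= n else [child])
        else:
            members = _leaves(Z, n, node)
            if len(members) >= min_module_size:
                clusters.append(members)
            else:
                unassigned.extend(members)

    labels = np.zeros(n, dtype=int)
    for cid, members in enumerate(clusters, start=1):
        labels[members] = cid

    # hybrid stage: adopt unassigned objects into compatible modules
    if clusters and unassigned:
        internal = np.full(len(clusters) + 1, np.nan)
        for cid, members in enumerate(clusters, start=1):
            if len(members) > 1:
                sub = dist_matrix[np.ix_(members, members)]
                internal[cid] = sub[np.triu_indices(len(members), k=1)].mean()
        for obj in sorted(unassigned):
            avg = np.array(
                [dist_matrix[obj, members].mean() for members in clusters]
            )
            best = int(np.argmin(avg))
            radius = internal[best + 1]
            if np.isnan(radius):
                radius = np.nanmax(internal) if np.isfinite(np.nanmax(internal)) else 0.0
            if radius > 0 and avg[best] <= 1.5 * radius:
                labels[obj] = best + 1

    return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels by decreasing module size (ties by first
    appearance); 0 stays 0."""
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if len(ids) == 0:
        return labels
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    mapping = {int(ids[i]): rank + 1 for rank, i in enumerate(order)}
    out = labels.copy()
    for old, new in mapping.items():
        out[labels == old] = new
    return out


def _impute_rows(rows: np.ndarray) -> np.ndarray:
    """Row-internal linear interpolation of missing bins (edges constant)."""
    out = rows.copy()
    x = np.arange(rows.shape[1])
    for i in range(rows.shape[0]):
        missing = np.isnan(out[i])
        if missing.any() and not missing.all():
            good = ~missing
            out[i, missing] = np.interp(x[missing], x[good], out[i, good])
    return out


def cluster_modules(
    matrix: BinnedDensityMatrix,
    distance: str = "euclidean",
    linkage: str = "average",
    min_module_size: int = 20,
    deep_split: int = 2,
    impute_missing: bool = True,
    standardize: bool = False,
) -> ModuleAssignment:
    """Group regions into modules by methylation-profile shape.

    Rows with more than 50% missing bins (or any missing bin when
    ``impute_missing`` is off) are excluded to module 0. Remaining rows are
    imputed, pairwise distances computed (``euclidean`` or ``correlation``),
    agglomerated (``average`` or ``ward`` linkage), and cut with
    :func:`hybrid_tree_cut`.

    Clustering operates on raw density profiles by default, so both the
    methylation level and the along-gene shape inform module membership
    (flat-but-high genes form their own module instead of degenerating to
    amplified noise). Set ``standardize=True`` for pure shape clustering of
    rows with substantial internal variation.

    Raises
    ------
    ValueError
        When fewer than ``2 * min_module_size`` usable rows remain —
        lower ``min_module_size`` or relax the missing-data filter.
    """
    if distance not in ("euclidean", "correlation"):
        raise ValueError("distance must be 'euclidean' or 'correlation'")
    if linkage not in ("average", "ward"):
        raise ValueError("linkage must be 'average' or 'ward'")

    dens = matrix.density
    n_bins = dens.shape[1]
    missing_frac = np.isnan(dens).sum(axis=1) / n_bins
    usable = missing_frac <= 0.5 if impute_missing else missing_frac == 0.0
    labels_full = np.zeros(matrix.n_regions, dtype=int)
    idx = np.flatnonzero(usable)
    if len(idx) < 2 * min_module_size:
        raise ValueError(
            f"only {len(idx)} usable regions for min_module_size={min_module_size}; "
            "need at least 2*min_module_size — lower min_module_size or allow imputation"
        )

    rows = _impute_rows(dens[idx]) if impute_missing else dens[idx].copy()
    if standardize:
        mu = rows.mean(axis=1, keepdims=True)
        sd = rows.std(axis=1, keepdims=True)
        rows = np.where(sd > 0, (rows - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    condensed = pdist(rows, metric=distance)
    condensed = np.nan_to_num(condensed, nan=0.0)  # constant rows under correlation
    Z = scipy_linkage(condensed, method=linkage)
    labels = hybrid_tree_cut(Z, squareform(condensed), min_module_size, deep_split)
    labels_full[idx] = labels
    return ModuleAssignment(
        region_ids=matrix.region_ids.astype(str),
        labels=labels_full,
        distance=distance,
        linkage=linkage,
        min_module_size=min_module_size,
        deep_split=deep_split,
    )


def module_profiles(matrix: BinnedDensityMatrix, assignment: ModuleAssignment) -> pd.DataFrame:
    """Per-module consensus profile: unweighted per-bin mean density over
    member regions (module 0 excluded). Returns a tidy frame with columns
    module_id, n_members, bin_0..bin_{B-1}."""
    dens = matrix.density
    records = []
    for module_id in range(1, assignment.n_modules + 1):
        members = assignment.labels == module_id
        if not members.any():
            continue
        with np.errstate(invalid="ignore"):
            block = dens[members]
            cnt = (~np.isnan(block)).sum(axis=0)
            consensus = np.where(
                cnt > 0, np.nansum(block, axis=0) / np.maximum(cnt, 1), np.nan
            )
        rec = {"module_id": module_id, "n_members": int(members.sum())}
        rec.update({f"bin_{j}": consensus[j] for j in range(dens.shape[1])})
        records.append(rec)
    if not records:
        raise ValueError("assignment contains no modules")
    return pd.DataFrame.from_records(records)
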